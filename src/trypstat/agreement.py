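"""Cross-engine and cross-treatment agreement statistics: Venn partitions of
gene-symbol sets, log-log regression of peptide counts per symbol between
two count tables, and per-symbol observation-frequency contrasts across
treatments."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inference import bh_qvalues

__all__ = [
    "VennPartition",
    "RegressionResult",
    "venn",
    "loglog_count_regression",
    "treatment_contrast",
]


@dataclass
class VennPartition:
    labels: tuple[str, ...]
    regions: dict[tuple[bool, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def region(self, *labels: str) -> int:
        """Count of the region containing exactly the given labels."""
        pattern = tuple(lab in labels for lab in self.labels)
        return self.regions.get(pattern, 0)


def venn(sets: dict[str, set]) -> VennPartition:
    """Exact membership partition of 2 or 3 symbol sets.

    Every element of the union lands in exactly one of the 2^k - 1 regions.
    """
    labels = tuple(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn supports 2 or 3 sets")
    union = set().union(*sets.values())
    regions = {
        pattern: 0
        for pattern in product([False, True], repeat=len(labels))
        if any(pattern)
    }
    for element in union:
        pattern = tuple(element in sets[lab] for lab in labels)
        regions[pattern] += 1
    return VennPartition(labels=labels, regions=regions)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float
    n: int


def loglog_count_regression(
    counts_a: dict[str, int] | pd.Series,
    counts_b: dict[str, int] | pd.Series,
    min_count_a: int = 3,
) -> RegressionResult:
    """OLS of ln(count_b) on ln(count_a) over shared gene symbols.

    Restricted to symbols with ``count_a >= min_count_a`` (the first table's
    confident set) and ``count_b >= 1``; symbols with a zero count in either
    table are excluded since the regression is on log counts.
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    shared = a.index.intersection(b.index)
    keep = shared[(a[shared] >= min_count_a) & (b[shared] >= 1)]
    if len(keep) < 3:
        raise ValueError(
            f"need >= 3 shared symbols after restriction, got {len(keep)}"
        )
    x = np.log(a[keep].to_numpy())
    y = np.log(b[keep].to_numpy())
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        df_residual=int(model.df_resid),
        p_value=float(model.f_pvalue),
        n=len(keep),
    )


def treatment_contrast(
    counts_by_treatment: dict[str, dict[str, int] | pd.Series],
) -> pd.DataFrame:
    """Per-symbol chi-square contrast of observation counts across treatments.

    For each symbol, the observed counts per treatment are tested against the
    expectation proportional to each treatment's total (df = k - 1); p-values
    are BH-adjusted over symbols.  The statistic is symmetric in treatment
    labels.
    """
    treatments = list(counts_by_treatment)
    if len(treatments) < 2:
        raise ValueError("need >= 2 treatments")
    table = pd.DataFrame(
        {t: pd.Series(c, dtype=float) for t, c in counts_by_treatment.items()}
    ).fillna(0.0)
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every treatment needs a positive total count")
    frac = totals / totals.sum()
    obs = table.to_numpy()
    expected = np.outer(obs.sum(axis=1), frac.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum((obs - expected) ** 2 / expected, axis=1)
    p = stats.chi2.sf(chi2, df=len(treatments) - 1)
    out = table.astype(int).copy()
    out["chi_square"] = chi2
    out["p_value"] = p
    out["q_value"] = bh_qvalues(p)
    out.index.name = "gene_symbol"
    return out.reset_index()
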