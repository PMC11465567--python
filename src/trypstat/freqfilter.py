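"""Observation-frequency correction against control count tables.

Two controls are applied in sequence, mirroring the accounting order of the
study design: first the blank-injection (analytical noise) control at the
peptide-sequence level, then the random-spectrum Monte Carlo (statistical)
control at the gene-symbol level.  Each is a one-degree-of-freedom chi-square
test of the experimental observation count against the count expected under
the control's rate; a key is retained only when the statistic reaches the
threshold (default chi-square >= 9, i.e. p <= 0.0027) *and* the experimental
normalized frequency exceeds the control's.

Expected counts use a pseudocount floor: E = max(total_exp * count_ctrl /
total_ctrl, pseudocount).  The floor (default half an expected count) gives
keys never seen in the control a finite expectation — three or more
experimental observations then resolve them — while keys the control did see
are judged against the control's actual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHI2_THRESHOLD",
    "FilterDecision",
    "chi_square_frequency",
    "filter_against_control",
    "peptide_counts",
    "symbol_counts",
]

CHI2_THRESHOLD = 9.0
PSEUDOCOUNT = 0.5

REASONS = ("PASS", "NOT_RESOLVED_FROM_NOISE", "NOT_RESOLVED_FROM_RANDOM",
           "HARD_BLANK_OVERLAP")


@dataclass
class FilterDecision:
    key: str
    chi_square: float
    p_value: float
    retained: bool
    reason: str


def chi_square_frequency(
    count_exp, total_exp, count_ctrl, total_ctrl, pseudocount: float = PSEUDOCOUNT
):
    """Chi-square (1 df) of an observed experimental count against the count
    expected from the control rate.  Vectorized over counts.

    Returns ``(chi_square, p_value)`` with p from the chi-square survival
    function at one degree of freedom.
    """
    if np.any(np.asarray(total_exp) <= 0) or np.any(np.asarray(total_ctrl) <= 0):
        raise ValueError("totals must be positive")
    count_exp = np.asarray(count_exp, dtype=float)
    count_ctrl = np.asarray(count_ctrl, dtype=float)
    if np.any(count_exp < 0) or np.any(count_ctrl < 0):
        raise ValueError("counts must be non-negative")
    expected = np.maximum(total_exp * count_ctrl / total_ctrl, pseudocount)
    chi2 = (count_exp - expected) ** 2 / expected
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def peptide_counts(psms: pd.DataFrame) -> pd.DataFrame:
    """Observation (spectral) counts per peptide sequence."""
    counts = psms.groupby("peptide", as_index=False).size()
    counts = counts.rename(columns={"peptide": "key", "size": "count"})
    counts.attrs["total"] = int(len(psms))
    return counts


def symbol_counts(psms: pd.DataFrame, peptide_to_symbols: dict[str, set[str]]) -> pd.DataFrame:
    """Observation counts per gene symbol (a shared peptide counts toward
    every symbol whose digest contains it)."""
    pep = peptide_counts(psms)
    rows: dict[str, int] = {}
    for key, count in zip(pep["key"], pep["count"]):
        for sym in peptide_to_symbols.get(key, ()):
            rows[sym] = rows.get(sym, 0) + int(count)
    out = pd.DataFrame({"key": list(rows), "count": list(rows.values())})
    out.attrs["total"] = int(len(psms))
    return out


def filter_against_control(
    pool: pd.DataFrame,
    control_table: pd.DataFrame,
    threshold: float = CHI2_THRESHOLD,
    mode: str = "chi2",
    level: str = "peptide",
    reason: str = "NOT_RESOLVED_FROM_NOISE",
    peptide_to_symbols: dict[str, set[str]] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard pool entries whose observation frequency is not resolved from
    the control.

    ``level`` selects the key: ``peptide`` filters peptide sequences directly;
    ``symbol`` aggregates experimental counts to gene symbols (via
    ``peptide_to_symbols``) and discards every peptide of an unresolved
    symbol (a peptide survives if any of its symbols is resolved).

    ``mode='chi2'`` retains a key iff chi-square >= ``threshold`` and the
    experimental normalized frequency exceeds the control's; ``mode='hard'``
    discards any key present in the control at all.

    Returns ``(retained_pool, decisions)``; input rows are conserved between
    the retained pool and the discarded set.
    """
    if mode not in ("chi2", "hard"):
        raise ValueError(f"unknown mode {mode!r}")
    if level not in ("peptide", "symbol"):
        raise ValueError(f"unknown level {level!r}")

    if level == "peptide":
        exp = peptide_counts(pool)
    else:
        if peptide_to_symbols is None:
            raise ValueError("symbol-level filtering needs peptide_to_symbols")
        exp = symbol_counts(pool, peptide_to_symbols)
    total_exp = exp.attrs["total"]
    total_ctrl = int(control_table.attrs.get(
        "total", control_table["count"].sum()
    ))

    merged = exp.merge(
        control_table.rename(columns={"count": "count_ctrl"}),
        on="key", how="left",
    )
    merged["count_ctrl"] = merged["count_ctrl"].fillna(0).astype(float)

    if mode == "hard":
        chi2 = np.zeros(len(merged))
        p = np.ones(len(merged))
        retained = merged["count_ctrl"].to_numpy() == 0
        why = np.where(retained, "PASS", "HARD_BLANK_OVERLAP")
    else:
        chi2, p = chi_square_frequency(
            merged["count"], total_exp, merged["count_ctrl"], total_ctrl,
            pseudocount=pseudocount,
        )
        exp_rate = merged["count"].to_numpy() / total_exp
        ctrl_rate = merged["count_ctrl"].to_numpy() / total_ctrl
        retained = (chi2 >= threshold) & (exp_rate > ctrl_rate)
        why = np.where(retained, "PASS", reason)

    decisions = pd.DataFrame({
        "key": merged["key"],
        "count_experiment": merged["count"],
        "count_control": merged["count_ctrl"].astype(int),
        "chi_square": chi2,
        "p_value": p,
        "retained": retained,
        "reason": why,
    })

    if level == "peptide":
        keep_keys = set(decisions.loc[decisions["retained"], "key"])
        keep_mask = pool["peptide"].isin(keep_keys)
    else:
        kept_symbols = set(decisions.loc[decisions["retained"], "key"])
        keep = {
            pep for pep in pool["peptide"].unique()
            if peptide_to_symbols.get(pep, set()) & kept_symbols
        }
        keep_mask = pool["peptide"].isin(keep)
    retained_pool = pool[keep_mask].reset_index(drop=True)
    assert len(retained_pool) + int((~keep_mask).sum()) == len(pool)
    return retained_pool, decisions
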