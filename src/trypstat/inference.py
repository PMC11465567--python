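"""Protein inference: peptide-to-accession mapping, gene-symbol rollup,
score thresholds, protein p-value aggregation, and Benjamini-Hochberg FDR
q-values.

No parsimony grouping is applied: a peptide shared across gene symbols
counts toward every one of them, matching a counting scheme in which
peptides map to every accession whose digest contains them and accessions
collapse to symbols.  The protein p-value is Fisher's combination of the
best (minimum) p-value per distinct supporting peptide; it is computed for
the goodness-of-fit engine only, since the cross-correlation engine's score
is not a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import tryptic_digest

__all__ = [
    "Thresholds",
    "ProteinRollup",
    "digest_index",
    "apply_score_thresholds",
    "rollup",
    "aggregate_protein_p",
    "bh_qvalues",
    "tier_report",
]


@dataclass(frozen=True)
class Thresholds:
    """Score and FDR acceptance thresholds (all inclusive bounds)."""

    gof_peptide_p_max: float = 0.1
    xcorr_min: float = 2.0
    protein_q_max: float = 0.01
    min_peptides_tiers: tuple[int, ...] = (1, 2, 3)


@dataclass
class ProteinRollup:
    gene_symbol: str
    peptide_set: set[str] = field(default_factory=set)
    spectral_count: int = 0
    p_protein: float = 1.0
    q_value: float = 1.0

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_set)


def digest_index(
    database: dict[str, str],
    accession_map: dict[str, str],
    max_missed: int = 2,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Map every tryptic peptide of the database to its accessions and
    gene symbols."""
    pep_to_acc: dict[str, set[str]] = {}
    pep_to_sym: dict[str, set[str]] = {}
    for acc, seq in database.items():
        sym = accession_map.get(acc, acc)
        for rec in tryptic_digest(seq, max_missed=max_missed, compute_mh=False):
            pep_to_acc.setdefault(rec.sequence, set()).add(acc)
            pep_to_sym.setdefault(rec.sequence, set()).add(sym)
    return pep_to_acc, pep_to_sym


def apply_score_thresholds(
    pool: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Keep GOF PSMs with p <= gof_peptide_p_max and XCORR PSMs with
    score >= xcorr_min (both bounds inclusive)."""
    gof = pool["engine"] == "GOF"
    keep = (gof & (pool["score"] <= thresholds.gof_peptide_p_max)) | (
        ~gof & (pool["score"] >= thresholds.xcorr_min)
    )
    return pool[keep].reset_index(drop=True)


def aggregate_protein_p(peptide_p: np.ndarray | list[float]) -> float:
    """Fisher's method: -2 sum(ln p) on 2k degrees of freedom.

    With a single p-value this is the identity; p = 1 contributes nothing.
    """
    p = np.asarray(peptide_p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one peptide p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    statistic = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(statistic, df=2 * p.size))


def bh_qvalues(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order.

    q_(i) = min over j >= i of (m / j) * p_(j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rollup(
    pool: pd.DataFrame,
    pep_to_sym: dict[str, set[str]],
    compute_q: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll a corrected, thresholded PSM pool up to gene symbols.

    Returns ``(rollups, orphans)``.  ``rollups`` has one row per symbol with
    the distinct peptide count, total spectral count, the Fisher-aggregated
    protein p-value (GOF pools; 1.0 for XCORR pools) and its BH q-value.
    Peptides found in no accession's digest are routed to the orphan report,
    never dropped silently.
    """
    is_gof = bool((pool["engine"] == "GOF").all()) if len(pool) else True
    per_pep = pool.groupby("peptide").agg(
        count=("peptide", "size"), best_p=("score", "min")
    )
    orphan_keys = [k for k in per_pep.index if k not in pep_to_sym]
    orphans = (
        per_pep.loc[orphan_keys].reset_index()
        .rename(columns={"peptide": "key"})
    )

    sym_peps: dict[str, list[str]] = {}
    for pep in per_pep.index:
        for sym in pep_to_sym.get(pep, ()):
            sym_peps.setdefault(sym, []).append(pep)

    records = []
    for sym, peps in sym_peps.items():
        counts = per_pep.loc[peps, "count"]
        if is_gof:
            p_protein = aggregate_protein_p(per_pep.loc[peps, "best_p"].to_numpy())
        else:
            p_protein = 1.0
        records.append({
            "gene_symbol": sym,
            "n_peptides": len(peps),
            "spectral_count": int(counts.sum()),
            "p_protein": p_protein,
        })
    rollups = pd.DataFrame(
        records, columns=["gene_symbol", "n_peptides", "spectral_count", "p_protein"]
    )
    if compute_q and len(rollups):
        rollups["q_value"] = bh_qvalues(rollups["p_protein"].to_numpy())
    else:
        rollups["q_value"] = pd.Series(dtype=float)
    return rollups.sort_values("gene_symbol", ignore_index=True), orphans


def tier_report(
    rollups: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Symbol counts at each minimum-peptide tier, with and without the
    protein q-value cutoff."""
    rows = []
    for tier in thresholds.min_peptides_tiers:
        at_tier = rollups[rollups["n_peptides"] >= tier] if len(rollups) else rollups
        n_all = int(len(at_tier))
        n_q = int((at_tier["q_value"] <= thresholds.protein_q_max).sum()) if n_all else 0
        rows.append({
            "min_peptides": tier,
            "n_symbols": n_all,
            f"n_symbols_q_le_{thresholds.protein_q_max}": n_q,
        })
    return pd.DataFrame(rows)
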