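"""Best-fit-per-spectrum (BFPS) consolidation.

Each MS/MS spectrum may enter the raw tables with several ranked candidate
peptides; the consolidation keeps exactly one — the best-scoring candidate —
per spectrum per engine, so no spectrum can support more than one peptide in
an engine's pool.  Ties break deterministically on smallest absolute delta
mass, then lexicographically smallest peptide sequence, then smallest rank,
which makes the selected set invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .io import add_spectrum_key

__all__ = ["ConsolidatedPool", "select_bfps", "cross_engine_census"]


@dataclass
class ConsolidatedPool:
    engine: str
    psms: pd.DataFrame
    audit: dict

    def __post_init__(self) -> None:
        assert self.audit["input"] == self.audit["selected"] + self.audit["discarded"]


def _theoretical_mh(psms: pd.DataFrame) -> np.ndarray:
    """Theoretical MH per row from peptide + mods, cached per unique pair."""
    cache: dict[tuple[str, str], float] = {}
    out = np.empty(len(psms), dtype=float)
    mods_tab = chem.STANDARD_MODIFICATIONS
    for i, (pep, mods) in enumerate(zip(psms["peptide"], psms["mods"])):
        key = (pep, mods)
        mh = cache.get(key)
        if mh is None:
            modlist = []
            if mods:
                for item in mods.split(";"):
                    pos, name = item.split(":")
                    modlist.append((int(pos), mods_tab[name]))
            try:
                mh = chem.peptide_mh(pep, modlist)
            except ValueError:
                mh = np.nan  # unknown residue: no delta available for ties
            cache[key] = mh
        out[i] = mh
    return out


def select_bfps(psms: pd.DataFrame, engine: str) -> ConsolidatedPool:
    """Keep the single best-scoring candidate per spectrum key.

    GOF pools minimize the p-value; XCORR pools maximize the score.  Raises
    on a pool containing rows from a different engine.
    """
    if engine not in ("GOF", "XCORR"):
        raise ValueError(f"unknown engine {engine!r}")
    if (psms["engine"] != engine).any():
        found = sorted(psms["engine"].unique())
        raise ValueError(f"mixed engines in pool: {found}, expected {engine}")
    pool = add_spectrum_key(psms)
    pool["_abs_delta"] = np.abs(
        pool["precursor_mh"].to_numpy() - _theoretical_mh(pool)
    )
    ascending_score = engine == "GOF"
    ordered = pool.sort_values(
        ["spectrum_key", "score", "_abs_delta", "peptide", "rank"],
        ascending=[True, ascending_score, True, True, True],
        kind="mergesort",
        na_position="last",
    )
    selected = ordered.drop_duplicates("spectrum_key", keep="first")
    selected = selected.drop(columns=["_abs_delta"]).reset_index(drop=True)
    audit = {
        "input": len(psms),
        "selected": len(selected),
        "discarded": len(psms) - len(selected),
    }
    return ConsolidatedPool(engine=engine, psms=selected, audit=audit)


def cross_engine_census(
    pool_gof: ConsolidatedPool, pool_xcorr: ConsolidatedPool
) -> pd.DataFrame:
    """Per-spectrum assignment comparison between the two engines.

    Returns one row per spectrum key seen by either engine with the peptide
    each engine assigned (including modifications) and an agreement flag;
    spectra seen by only one engine never agree.
    """
    def keyed(pool: ConsolidatedPool, name: str) -> pd.DataFrame:
        df = pool.psms
        assigned = df["peptide"].astype(str) + "|" + df["mods"].astype(str)
        return pd.DataFrame({
            "spectrum_key": df["spectrum_key"],
            name: assigned.to_numpy(),
        })

    census = keyed(pool_gof, "peptide_gof").merge(
        keyed(pool_xcorr, "peptide_xcorr"), on="spectrum_key", how="outer"
    )
    census["agree"] = (
        census["peptide_gof"].notna()
        & census["peptide_xcorr"].notna()
        & (census["peptide_gof"] == census["peptide_xcorr"])
    )
    return census
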