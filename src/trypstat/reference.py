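"""Published reference counts from a full-scale plasma digestion study.

These tables hold the per-treatment accounting of a 273-run, 5.4-million
MS/MS plasma study (trypsin alone vs DTT reduction vs reduction +
alkylation, 91 runs each) and its per-treatment albumin spectral counts.
They are inputs for validating the accounting arithmetic and the simulator's
albumin-suppression calibration — the pipeline itself never reads them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_accounting",
    "reference_engine_totals",
    "reference_albumin_counts",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("trypstat.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reference_accounting() -> pd.DataFrame:
    """Per-treatment accounting of the goodness-of-fit engine: MS runs,
    MS/MS counts, matched distinct spectra, and counts after each
    correction stage."""
    return _load("reference_accounting_gof.tsv")


def reference_engine_totals() -> pd.DataFrame:
    """Study-wide MS/MS totals and score-accepted counts per engine."""
    return _load("reference_engine_totals.tsv")


def reference_albumin_counts() -> pd.DataFrame:
    """Albumin spectral counts per digestion treatment and engine."""
    return _load("reference_albumin_counts.tsv")
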