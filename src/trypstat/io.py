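"""Readers and writers for the canonical PSM table dialect, FASTA databases
with accession-to-gene-symbol maps, and observation-frequency tables.

The PSM dialect is UTF-8 TSV with header columns::

    run_id  scan  engine  peptide  mods  charge  precursor_mh  intensity  score  rank  treatment

``mods`` is a semicolon-joined list of ``pos:name`` with 1-based residue
positions (empty string for an unmodified peptide).  ``engine`` is ``GOF``
(goodness-of-fit style, score is a p-value in (0, 1]) or ``XCORR``
(cross-correlation style, score >= 0).  Spectrum keys are ``run_id:scan`` and
must be globally unique within an engine's pool after consolidation.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PSM_COLUMNS",
    "ENGINES",
    "TREATMENTS",
    "PSMValidationError",
    "add_spectrum_key",
    "validate_psm_table",
    "read_psm_table",
    "write_psm_table",
    "concat_runs",
    "read_fasta_with_map",
    "write_fasta",
    "write_accession_map",
    "read_frequency_table",
    "write_frequency_table",
]

PSM_COLUMNS = [
    "run_id", "scan", "engine", "peptide", "mods", "charge",
    "precursor_mh", "intensity", "score", "rank", "treatment",
]
ENGINES = ("GOF", "XCORR")
TREATMENTS = ("T", "DT", "DAT", "BLANK", "RANDOM")


class PSMValidationError(ValueError):
    """A PSM table violated the dialect contract."""


def add_spectrum_key(psms: pd.DataFrame) -> pd.DataFrame:
    """Attach the globally unique spectrum key ``run_id:scan``."""
    out = psms.copy()
    out["spectrum_key"] = (
        out["run_id"].astype(str) + ":" + out["scan"].astype(str)
    )
    return out


def validate_psm_table(psms: pd.DataFrame, path: str | os.PathLike = "<memory>") -> None:
    """Raise :class:`PSMValidationError` on any dialect violation."""
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise PSMValidationError(f"{path}: missing required column(s) {missing}")
    bad_engine = ~psms["engine"].isin(ENGINES)
    if bad_engine.any():
        rows = psms.index[bad_engine][:5].tolist()
        raise PSMValidationError(f"{path}: unknown engine at rows {rows}")
    bad_treat = ~psms["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        rows = psms.index[bad_treat][:5].tolist()
        raise PSMValidationError(f"{path}: unknown treatment at rows {rows}")
    bad_charge = ~psms["charge"].isin((2, 3))
    if bad_charge.any():
        rows = psms.index[bad_charge][:5].tolist()
        raise PSMValidationError(f"{path}: charge outside {{2,3}} at rows {rows}")
    gof = psms["engine"] == "GOF"
    bad_gof = gof & ~((psms["score"] > 0) & (psms["score"] <= 1))
    if bad_gof.any():
        rows = psms.index[bad_gof][:5].tolist()
        raise PSMValidationError(
            f"{path}: GOF score outside (0, 1] at rows {rows}"
        )
    bad_xc = ~gof & (psms["score"] < 0)
    if bad_xc.any():
        rows = psms.index[bad_xc][:5].tolist()
        raise PSMValidationError(f"{path}: negative XCORR score at rows {rows}")
    nonrandom = psms["treatment"] != "RANDOM"
    bad_int = nonrandom & ~(psms["intensity"] > 0)
    if bad_int.any():
        rows = psms.index[bad_int][:5].tolist()
        raise PSMValidationError(
            f"{path}: non-positive intensity at rows {rows}"
        )
    dup = psms.duplicated(subset=["run_id", "scan", "engine", "rank"])
    if dup.any():
        rows = psms.index[dup][:5].tolist()
        raise PSMValidationError(
            f"{path}: duplicate (run_id, scan, engine, rank) at rows {rows}"
        )


def read_psm_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate one PSM table; malformed tables raise with context."""
    psms = pd.read_csv(
        path, sep="\t",
        dtype={"run_id": str, "mods": str, "engine": str,
               "peptide": str, "treatment": str},
        keep_default_na=False,
    )
    for col in ("scan", "charge", "rank"):
        if col in psms.columns:
            psms[col] = psms[col].astype(np.int64)
    for col in ("precursor_mh", "intensity", "score"):
        if col in psms.columns:
            psms[col] = psms[col].astype(float)
    validate_psm_table(psms, path)
    return psms


def write_psm_table(psms: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a PSM table in the canonical dialect with a stable row order."""
    validate_psm_table(psms, path)
    out = psms[PSM_COLUMNS].sort_values(
        ["run_id", "scan", "engine", "rank"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)


def concat_runs(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-run PSM tables, refusing duplicated spectrum keys.

    Loading the same run twice is an error: spectrum keys must stay globally
    unique across the pooled study.
    """
    pooled = pd.concat(list(tables), ignore_index=True)
    dup = pooled.duplicated(subset=["run_id", "scan", "engine", "rank"])
    if dup.any():
        run = pooled.loc[dup.idxmax(), "run_id"]
        raise PSMValidationError(
            f"duplicate spectrum keys on concat (run {run!r} loaded twice?)"
        )
    return pooled


def read_fasta_with_map(
    fasta_path: str | os.PathLike,
    map_path: str | os.PathLike | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Load a protein database plus accession → gene-symbol map.

    The accession is the first whitespace-delimited token of the FASTA header.
    Accessions absent from the map fall back to the accession string itself as
    the symbol (the convention for loci with no annotated symbol).
    """
    database: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        acc = record.id
        if acc in database:
            raise ValueError(f"duplicated accession {acc!r} in {fasta_path}")
        database[acc] = str(record.seq)
    if not database:
        raise ValueError(f"empty FASTA {fasta_path}")

    accession_map: dict[str, str] = {}
    if map_path is not None:
        mapping = pd.read_csv(
            map_path, sep="\t", dtype=str, keep_default_na=False
        )
        if list(mapping.columns[:2]) != ["accession", "gene_symbol"]:
            raise ValueError(
                f"{map_path}: expected columns accession, gene_symbol"
            )
        accession_map = dict(
            zip(mapping["accession"], mapping["gene_symbol"])
        )
    full_map = {acc: accession_map.get(acc, acc) for acc in database}
    return database, full_map


def write_fasta(database: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in database.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_accession_map(accession_map: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"accession": list(accession_map), "gene_symbol": list(accession_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a frequency table: columns ``key``, ``count``; total in attrs."""
    table = pd.read_csv(path, sep="\t", dtype={"key": str}, keep_default_na=False)
    if "key" not in table.columns or "count" not in table.columns:
        raise ValueError(f"{path}: expected columns key, count")
    if "total" in table.columns:
        table.attrs["total"] = int(table["total"].iloc[0])
        table = table.drop(columns=["total"])
    else:
        table.attrs["total"] = int(table["count"].sum())
    return table


def write_frequency_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table[["key", "count"]].copy()
    out["total"] = int(table.attrs.get("total", out["count"].sum()))
    out.sort_values("key", kind="mergesort").to_csv(path, sep="\t", index=False)
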