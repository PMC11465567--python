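"""End-to-end orchestration: simulate -> consolidate -> correct -> infer ->
compare, with a run manifest and a digestion-treatment accounting table.

The accounting table mirrors the per-treatment bookkeeping of a
digestion-condition comparison: MS runs, MS/MS count, matched distinct
spectra, counts after best-fit-per-spectrum consolidation, after the blank
(noise) correction, after the random-spectrum (Monte Carlo) correction,
after score thresholds, and the gene symbols observed — weakly decreasing
left to right from the matched column onward, with a totals row equal to the
column sums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .bfps import ConsolidatedPool, cross_engine_census, select_bfps
from .chem import STANDARD_MODIFICATIONS, peptide_mh
from .freqfilter import CHI2_THRESHOLD, PSEUDOCOUNT, filter_against_control, peptide_counts
from .inference import Thresholds, apply_score_thresholds, digest_index, rollup, tier_report
from .agreement import loglog_count_regression, treatment_contrast, venn
from .simulate import (
    SimParams,
    TreatmentDesign,
    build_peptide_pool,
    database_dicts,
    generate_blank_runs,
    generate_database,
    generate_random_matches,
    make_noise_pool,
    simulate_runs,
    simulate_treatment_digest,
)

__all__ = [
    "Config",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "accounting_report",
    "distribution_summary",
]

ACCOUNTING_COLUMNS = [
    "treatment", "ms_runs", "msms_count", "matched_distinct_spectra",
    "bfps", "noise_corrected", "random_corrected", "score_accepted",
    "symbols_n_ge_1",
]


@dataclass
class Config:
    """Structured run configuration; every study default lives here."""

    sim: SimParams = field(default_factory=SimParams)
    design: TreatmentDesign = field(default_factory=TreatmentDesign)
    thresholds: Thresholds = field(default_factory=Thresholds)
    chi2_threshold: float = CHI2_THRESHOLD
    pseudocount: float = PSEUDOCOUNT
    blank_mode: str = "chi2"  # or "hard": absolute discard of blank overlap
    blank_level: str = "peptide"
    random_level: str = "symbol"
    scale: float = 1.0  # multiplier on simulated spectrum counts

    def scaled(self) -> "Config":
        if self.scale == 1.0:
            return self
        sim = dataclasses.replace(
            self.sim,
            spectra_per_run=max(10, int(self.sim.spectra_per_run * self.scale)),
            blank_spectra_per_run=max(
                10, int(self.sim.blank_spectra_per_run * self.scale)
            ),
        )
        design = dataclasses.replace(
            self.design,
            n_random_spectra=max(1000, int(self.design.n_random_spectra * self.scale)),
        )
        return dataclasses.replace(self, sim=sim, design=design, scale=1.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        data = dict(data)
        sim_data = dict(data.pop("sim", {}))
        for key in ("missed_cleavage_penalty", "mh_window", "isotope_classes",
                    "isotope_class_probs", "gof_true_beta", "xcorr_true",
                    "xcorr_false"):
            if key in sim_data:
                sim_data[key] = tuple(sim_data[key])
        sim = SimParams(**sim_data)
        dsg = data.pop("design", {})
        for key in ("treatments", "blocks"):
            if key in dsg:
                dsg[key] = tuple(dsg[key])
        design = TreatmentDesign(**dsg)
        thr = data.pop("thresholds", {})
        if "min_peptides_tiers" in thr:
            thr["min_peptides_tiers"] = tuple(thr["min_peptides_tiers"])
        return cls(sim=sim, design=design, thresholds=Thresholds(**thr), **data)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    seed: int
    config: dict
    stage_counts: dict
    accounting: pd.DataFrame
    timings: dict = field(default_factory=dict)
    file_digests: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "accounting": self.accounting.to_dict(orient="records"),
            "file_digests": self.file_digests,
        }
        return json.dumps(payload, indent=2, default=str)


@dataclass
class PipelineResult:
    config: Config
    seed: int
    proteins: list
    database: dict
    accession_map: dict
    truth: pd.DataFrame
    raw: dict  # engine -> raw PSM table
    consolidated: dict  # engine -> ConsolidatedPool
    noise_corrected: dict
    random_corrected: dict
    accepted: dict
    blank_psms: pd.DataFrame
    random_table: object
    decisions: dict
    rollups: dict  # engine -> rollup table
    orphans: dict
    tier_reports: dict
    rollups_by_treatment: dict  # (engine, treatment) -> rollup table
    census: pd.DataFrame
    manifest: RunManifest
    pep_to_sym: dict


def _symbol_counts_at(pool: pd.DataFrame, pep_to_sym: dict, min_peptides: int = 1):
    """symbol -> spectral count for symbols with >= min_peptides distinct
    peptides, from a PSM pool."""
    per_pep = pool.groupby("peptide").size()
    sym_count: dict[str, int] = {}
    sym_npep: dict[str, int] = {}
    for pep, count in per_pep.items():
        for sym in pep_to_sym.get(pep, ()):
            sym_count[sym] = sym_count.get(sym, 0) + int(count)
            sym_npep[sym] = sym_npep.get(sym, 0) + 1
    return {
        s: c for s, c in sym_count.items() if sym_npep[s] >= min_peptides
    }


def run_pipeline(
    config: Config | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    write_tables: bool = False,
) -> PipelineResult:
    """Execute every stage in order on a fresh simulation.

    Deterministic under ``(config, seed)``.  With ``outdir`` set, stage
    summaries (and, with ``write_tables``, the full PSM tables) are written
    and digested into the manifest.
    """
    config = (config or Config()).scaled()
    params, design, thresholds = config.sim, config.design, config.thresholds
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- simulate ---------------------------------------------------------
    proteins = generate_database(params.n_proteins, params, seed)
    database, amap = database_dicts(proteins, params=params)
    base_pool = build_peptide_pool(proteins, params, seed)
    noise_pool = make_noise_pool(params, seed)
    pools = {
        t: simulate_treatment_digest(proteins, t, params, seed, base_pool=base_pool)
        for t in design.treatments
    }
    psm_frames, truth_frames = [], []
    for t in design.treatments:
        psms_t, truth_t = simulate_runs(pools[t], design, params, seed, noise_pool)
        psm_frames.append(psms_t)
        truth_frames.append(truth_t)
    all_psms = pd.concat(psm_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    blank_psms = generate_blank_runs(
        design, params, seed, noise_pool, contaminant_pool=pools[design.treatments[-1]]
    )
    random_table = generate_random_matches(
        pools[design.treatments[-1]], design.n_random_spectra, seed
    )
    timings["simulate"] = time.perf_counter() - t0

    pep_to_acc, pep_to_sym = digest_index(database, amap, params.max_missed)

    # --- consolidate, correct, infer (per engine) -------------------------
    raw, consolidated, noise_corr, random_corr, accepted = {}, {}, {}, {}, {}
    decisions, rollups, orphans, tiers = {}, {}, {}, {}
    rollups_by_treatment = {}
    for engine in ("GOF", "XCORR"):
        t1 = time.perf_counter()
        raw[engine] = all_psms[all_psms["engine"] == engine].reset_index(drop=True)
        consolidated[engine] = select_bfps(raw[engine], engine)
        pool = consolidated[engine].psms

        blank_control = peptide_counts(
            blank_psms[blank_psms["engine"] == engine]
        )
        pool, blank_dec = filter_against_control(
            pool, blank_control,
            threshold=config.chi2_threshold, mode=config.blank_mode,
            level=config.blank_level, reason="NOT_RESOLVED_FROM_NOISE",
            peptide_to_symbols=pep_to_sym, pseudocount=config.pseudocount,
        )
        noise_corr[engine] = pool

        pool, rand_dec = filter_against_control(
            pool, random_table.per_symbol,
            threshold=config.chi2_threshold, mode="chi2",
            level=config.random_level, reason="NOT_RESOLVED_FROM_RANDOM",
            peptide_to_symbols=pep_to_sym, pseudocount=config.pseudocount,
        )
        random_corr[engine] = pool
        decisions[engine] = {"blank": blank_dec, "random": rand_dec}

        accepted[engine] = apply_score_thresholds(pool, thresholds)
        rollups[engine], orphans[engine] = rollup(accepted[engine], pep_to_sym)
        tiers[engine] = tier_report(rollups[engine], thresholds)
        for t in design.treatments:
            sub = accepted[engine][accepted[engine]["treatment"] == t]
            rollups_by_treatment[(engine, t)], _ = rollup(sub, pep_to_sym)
        timings[f"engine_{engine}"] = time.perf_counter() - t1

    census = cross_engine_census(consolidated["GOF"], consolidated["XCORR"])

    # --- accounting -------------------------------------------------------
    rows = []
    for t in design.treatments:
        row = {"treatment": t, "ms_runs": design.runs_per_treatment,
               "msms_count": design.runs_per_treatment * params.spectra_per_run}
        for name, stage in (
            ("matched_distinct_spectra", raw), ("bfps", None),
            ("noise_corrected", noise_corr), ("random_corrected", random_corr),
            ("score_accepted", accepted),
        ):
            if name == "matched_distinct_spectra":
                sub = raw["GOF"]
                row[name] = int(
                    sub.loc[sub["treatment"] == t]
                    .groupby(["run_id", "scan"]).ngroups
                )
            elif name == "bfps":
                sub = consolidated["GOF"].psms
                row[name] = int((sub["treatment"] == t).sum())
            else:
                sub = stage["GOF"]
                row[name] = int((sub["treatment"] == t).sum())
        row["symbols_n_ge_1"] = len(
            _symbol_counts_at(
                accepted["GOF"][accepted["GOF"]["treatment"] == t], pep_to_sym
            )
        )
        rows.append(row)
    accounting = accounting_report(pd.DataFrame(rows, columns=ACCOUNTING_COLUMNS))

    stage_counts = {
        "raw": {e: len(raw[e]) for e in raw},
        "consolidated": {e: consolidated[e].audit for e in consolidated},
        "noise_corrected": {e: len(noise_corr[e]) for e in noise_corr},
        "random_corrected": {e: len(random_corr[e]) for e in random_corr},
        "accepted": {e: len(accepted[e]) for e in accepted},
        "symbols": {e: len(rollups[e]) for e in rollups},
    }
    manifest = RunManifest(
        seed=seed, config=config.to_dict(), stage_counts=stage_counts,
        accounting=accounting, timings=timings,
    )

    result = PipelineResult(
        config=config, seed=seed, proteins=proteins, database=database,
        accession_map=amap, truth=truth, raw=raw, consolidated=consolidated,
        noise_corrected=noise_corr, random_corrected=random_corr,
        accepted=accepted, blank_psms=blank_psms, random_table=random_table,
        decisions=decisions, rollups=rollups, orphans=orphans,
        tier_reports=tiers, rollups_by_treatment=rollups_by_treatment,
        census=census, manifest=manifest, pep_to_sym=pep_to_sym,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), write_tables)
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(result: PipelineResult, outdir: Path, write_tables: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(result.database, outdir / "database.fasta")
    tio.write_accession_map(result.accession_map, outdir / "accession_map.tsv")
    result.manifest.accounting.to_csv(
        outdir / "accounting.tsv", sep="\t", index=False
    )
    for engine in result.rollups:
        result.rollups[engine].to_csv(
            outdir / f"rollup_{engine}.tsv", sep="\t", index=False
        )
        result.tier_reports[engine].to_csv(
            outdir / f"tiers_{engine}.tsv", sep="\t", index=False
        )
        for stage, dec in result.decisions[engine].items():
            dec.to_csv(
                outdir / f"decisions_{stage}_{engine}.tsv", sep="\t", index=False
            )
        if write_tables:
            tio.write_psm_table(
                result.raw[engine], outdir / f"psms_raw_{engine}.tsv"
            )
            tio.write_psm_table(
                result.accepted[engine], outdir / f"psms_accepted_{engine}.tsv"
            )
    if write_tables:
        tio.write_psm_table(result.blank_psms, outdir / "psms_blank.tsv")
    tio.write_frequency_table(
        result.random_table.per_symbol, outdir / "random_matches_symbol.tsv"
    )
    result.manifest.file_digests = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file()
    }
    (outdir / "manifest.json").write_text(result.manifest.to_json())


def accounting_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a totals row and derived acceptance percentages.

    ``counts`` needs at least ``treatment``, ``msms_count`` and
    ``score_accepted`` columns (the layout produced by :func:`run_pipeline`,
    or any externally supplied per-treatment table in the same layout).  The
    derived percentage is accepted / total MS/MS, rounded to one decimal.
    """
    numeric = [c for c in counts.columns if c != "treatment"]
    total = {c: int(counts[c].sum()) for c in numeric}
    total["treatment"] = "Total"
    out = pd.concat([counts, pd.DataFrame([total])], ignore_index=True)
    out["accepted_pct_msms"] = (
        100.0 * out["score_accepted"] / out["msms_count"]
    ).round(1)
    return out


def recovery_metrics(result: PipelineResult, engine: str = "GOF") -> dict:
    """Ground-truth parameter-recovery readout of one pipeline run.

    Uses the simulator's per-spectrum truth table to score the corrected,
    thresholded inference: the fraction of truly present proteins (>= 3
    distinct sampled peptides) recovered at n_peptides >= 3 and q <= the
    protein q cutoff; the false-symbol fraction among recoveries; the
    fraction of noise-pool-only peptides removed by the blank filter; and
    whether any giant (random-match-inflated) symbol survived.
    """
    thresholds = result.config.thresholds
    truth = result.truth
    true_spectra = truth[truth["kind"] == "TRUE"]
    peptides_per_symbol = true_spectra.groupby("gene_symbol")["peptide"].nunique()
    ground_truth = set(peptides_per_symbol[peptides_per_symbol >= 3].index)

    rollups = result.rollups[engine]
    recovered = set(
        rollups.loc[
            (rollups["n_peptides"] >= 3)
            & (rollups["q_value"] <= thresholds.protein_q_max),
            "gene_symbol",
        ]
    )
    truly_present = set(true_spectra["gene_symbol"])
    false_symbols = recovered - truly_present

    noise_peps = set(truth.loc[truth["kind"] == "NOISE", "peptide"])
    noise_only = noise_peps - set(true_spectra["peptide"])
    consolidated = set(result.consolidated[engine].psms["peptide"])
    after_blank = set(result.noise_corrected[engine]["peptide"])
    noise_present = noise_only & consolidated
    noise_removed = noise_present - after_blank

    giants = {p.gene_symbol for p in result.proteins if p.is_giant}
    symbols_before_random = set().union(
        *(result.pep_to_sym.get(p, set())
          for p in result.noise_corrected[engine]["peptide"].unique())
    )
    return {
        "n_true_proteins_ge_3_peptides": len(ground_truth),
        "n_recovered": len(ground_truth & recovered),
        "recovery_rate": len(ground_truth & recovered) / max(len(ground_truth), 1),
        "false_symbol_fraction": len(false_symbols) / max(len(recovered), 1),
        "noise_peptides_present": len(noise_present),
        "noise_removal_rate": len(noise_removed) / max(len(noise_present), 1),
        "giants_before_random_filter": len(giants & symbols_before_random),
        "giants_recovered": len(giants & recovered),
    }


def distribution_summary(
    psms: pd.DataFrame, sample: int = 20000, seed: int = 0
) -> dict:
    """Shape summaries of a PSM pool (precursor mass, intensity, isotopes,
    charge, missed cleavages, CAM)."""
    from scipy import stats as sps

    from .bfps import _theoretical_mh
    from .chem import classify_delta

    rng = np.random.default_rng(seed)
    take = psms if len(psms) <= sample else psms.sample(
        sample, random_state=int(rng.integers(2**31))
    )
    theo = _theoretical_mh(take)
    bins = [
        classify_delta(o, t)
        for o, t in zip(take["precursor_mh"], theo)
        if np.isfinite(t)
    ]
    iso = pd.Series([b.isotope_class for b in bins if b.in_band])
    ln_int = np.log(take["intensity"].to_numpy())
    mh = theo[np.isfinite(theo)]
    mc = take["peptide"].map(lambda s: sum(c in "KR" for c in s[:-1]))
    return {
        "n": int(len(take)),
        "mh_fraction_1000_3000": float(((mh >= 1000) & (mh <= 3000)).mean()),
        "ln_intensity_mean": float(ln_int.mean()),
        "ln_intensity_sd": float(ln_int.std()),
        "ln_intensity_normality_p": float(
            sps.normaltest(ln_int[:5000]).pvalue
        ),
        "isotope_class_fractions": iso.value_counts(normalize=True).to_dict(),
        "isotope_012_fraction": float(iso.isin([0, 1, 2]).mean()),
        "charge2_fraction": float((take["charge"] == 2).mean()),
        "missed_cleavage_fractions": mc.value_counts(normalize=True).to_dict(),
        "cam_fraction": float(
            take["mods"].str.contains("CAM", regex=False).mean()
        ),
    }
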