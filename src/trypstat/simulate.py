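"""Synthetic digestion / LC-ESI-MS/MS study generator.

Emulates a three-treatment plasma digestion experiment read out by spectral
counting: an albumin-dominated protein database, disulfide-dependent peptide
accessibility per digestion treatment (T = trypsin alone, DT = DTT reduction
then trypsin, DAT = reduction, iodoacetamide alkylation, then trypsin),
multinomial spectral sampling competition, two search-engine score streams
(a goodness-of-fit p-value engine and a cross-correlation engine), blank-run
noise, and a random-spectrum Monte Carlo null whose matches accumulate in
giant proteins.

The generator's statistical shape targets: ~50% albumin mass fraction,
precursor MH mostly 1,000-3,000 Da, ln-intensities Gaussian over roughly
e4-e7 counts, precursor delta masses concentrated at the 0/+1/+2 Da isotope
classes, a 56%/44% 2+/3+ charge mix, and an albumin spectral-count T:DAT
ratio of about 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import NEUTRON_SPACING, PROTON, WATER, DEFAULT_TABLE, STANDARD_MODIFICATIONS

__all__ = [
    "SimProtein",
    "TreatmentDesign",
    "SimParams",
    "generate_database",
    "database_dicts",
    "build_peptide_pool",
    "simulate_treatment_digest",
    "make_noise_pool",
    "simulate_runs",
    "generate_blank_runs",
    "generate_random_matches",
    "RandomMatchTable",
]

TREATMENTS = ("T", "DT", "DAT")

# Approximate human proteome amino-acid frequencies (fractions).
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    0.083, 0.023, 0.054, 0.068, 0.036, 0.071, 0.026, 0.043, 0.057, 0.100,
    0.021, 0.041, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_MASS_LUT = np.zeros(256)
for _aa, _m in DEFAULT_TABLE.residue.items():
    _MASS_LUT[ord(_aa)] = _m
_CAM_DELTA = STANDARD_MODIFICATIONS["CAM"].delta


@dataclass
class SimProtein:
    """One database entry with its simulation ground truth."""

    accession: str
    gene_symbol: str
    sequence: str
    abundance_fraction: float
    n_disulfides: int
    shielded_spans: list[tuple[int, int]]
    is_albumin: bool = False
    is_giant: bool = False


@dataclass(frozen=True)
class TreatmentDesign:
    """The run layout: replicate blocks per elution scheme, per treatment.

    The default layout is one 4-replicate block, one 15-replicate block and
    three 24-step blocks per treatment (4 + 15 + 3x24 = 91 runs), three
    treatments (273 runs), plus 29 blank injections.
    """

    treatments: tuple[str, ...] = TREATMENTS
    blocks: tuple[int, ...] = (4, 15, 24, 24, 24)
    n_blank_runs: int = 29
    n_random_spectra: int = 150_000
    seed: int = 0

    @property
    def runs_per_treatment(self) -> int:
        return int(sum(self.blocks))

    @property
    def total_runs(self) -> int:
        return self.runs_per_treatment * len(self.treatments)


@dataclass(frozen=True)
class SimParams:
    """Tunable simulator parameters (defaults are the study conditions)."""

    n_proteins: int = 2000
    spectra_per_run: int = 2000

    # database shape
    albumin_fraction: float = 0.5
    albumin_length: int = 585
    albumin_disulfides: int = 17
    albumin_shield_coverage: float = 0.98
    abundance_exponent: float = 0.7
    protein_length_median: float = 360.0
    protein_length_sigma: float = 0.35
    n_giants: int = 40
    giant_length: int = 24_000
    giant_abundance_scale: float = 1e-3  # x smallest power-law share
    n_isoform_duplicates: int = 20
    mean_disulfides: float = 1.0
    shield_coverage_per_disulfide: float = 0.08

    # digestion / detectability
    max_missed: int = 2
    missed_cleavage_penalty: tuple[float, ...] = (1.0, 0.25, 0.04)
    flyability_sigma: float = 1.5
    detect_mh_center: float = 1700.0
    detect_mh_sigma: float = 0.45  # in ln-MH units
    mh_window: tuple[float, float] = (700.0, 4500.0)
    reduction_release: dict = field(
        default_factory=lambda: {"T": 0.15, "DT": 0.9, "DAT": 1.0}
    )
    cam_rate: dict = field(
        default_factory=lambda: {"T": 0.08, "DT": 0.08, "DAT": 0.90}
    )

    # spectrum properties
    p_charge2: float = 0.56
    log_intensity_mean: float = 5.5
    log_intensity_sd: float = 0.75
    isotope_classes: tuple[int, ...] = (0, 1, 2, -1, 3, -2, 4)
    isotope_class_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.02, 0.02, 0.005, 0.005)
    mass_jitter_sd: float = 0.03
    mass_jitter_max: float = 0.1

    # match composition and engine score models
    noise_fraction: float = 0.05  # contaminant spectra matching the noise pool
    random_match_fraction: float = 0.05  # spurious length-proportional matches
    p_correct: dict = field(default_factory=lambda: {"GOF": 0.92, "XCORR": 0.85})
    gof_true_beta: tuple[float, float] = (0.3, 8.0)
    xcorr_true: tuple[float, float] = (3.2, 0.8)
    xcorr_false: tuple[float, float] = (1.2, 0.5)
    multi_candidate_fraction: float = 0.3

    # blank runs
    noise_peptide_pool_size: int = 500
    blank_spectra_per_run: int = 400
    blank_contaminant_fraction: float = 0.02

    def __post_init__(self) -> None:
        probs = np.asarray(self.isotope_class_probs)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("isotope class probabilities must sum to 1")
        if not 0 <= self.p_charge2 <= 1:
            raise ValueError("p_charge2 must be in [0, 1]")


def _child(seed: int | np.random.SeedSequence, *key: int) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    return np.random.default_rng(np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=tuple(key)
    ))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def _shield_spans(rng: np.random.Generator, length: int, n_spans: int,
                  coverage: float) -> list[tuple[int, int]]:
    """n non-overlapping spans jointly covering ~``coverage`` of the chain."""
    if n_spans <= 0 or coverage <= 0 or length == 0:
        return []
    n_spans = min(n_spans, length)
    seg = length / n_spans
    span_len = coverage * seg
    spans = []
    for k in range(n_spans):
        lo = k * seg
        slack = seg - span_len
        start = lo + rng.uniform(0, slack) if slack > 0 else lo
        spans.append((int(round(start)), int(round(start + span_len))))
    return [(s, min(e, length)) for s, e in spans if e > s]


def generate_database(
    n_proteins: int = 2000,
    params: SimParams | None = None,
    seed: int = 0,
) -> list[SimProtein]:
    """Generate the synthetic protein database.

    One albumin analog holds ``albumin_fraction`` of the sample mass and
    carries the most disulfides; the remaining mass follows a power law over
    the other proteins; a small set of giant (TTN-scale) proteins is present
    in the search space at negligible abundance so that random matches can
    accumulate there.  Deterministic under ``seed``.
    """
    params = params or SimParams()
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    rng = _child(seed, 0)

    n_normal = n_proteins - 1 - params.n_giants
    lengths = np.exp(rng.normal(
        np.log(params.protein_length_median), params.protein_length_sigma,
        size=n_normal,
    )).astype(int)
    lengths = np.clip(lengths, 60, None)

    # power-law mass shares over the non-albumin, non-giant proteins
    ranks = np.arange(1, n_normal + 1, dtype=float)
    shares = ranks ** -params.abundance_exponent
    rng.shuffle(shares)
    giant_share = shares.min() * params.giant_abundance_scale
    others = np.concatenate([shares, np.full(params.n_giants, giant_share)])
    others = others / others.sum() * (1.0 - params.albumin_fraction)

    proteins: list[SimProtein] = []
    alb_seq = _random_sequence(rng, params.albumin_length)
    proteins.append(SimProtein(
        accession="ALB-SIM",
        gene_symbol="ALB",
        sequence=alb_seq,
        abundance_fraction=params.albumin_fraction,
        n_disulfides=params.albumin_disulfides,
        shielded_spans=_shield_spans(
            rng, len(alb_seq), params.albumin_disulfides,
            params.albumin_shield_coverage,
        ),
        is_albumin=True,
    ))
    for i in range(n_normal):
        n_ss = int(rng.poisson(params.mean_disulfides))
        length = int(lengths[i])
        coverage = min(params.shield_coverage_per_disulfide * n_ss, 0.5)
        proteins.append(SimProtein(
            accession=f"SIM{i:05d}",
            gene_symbol=f"GS{i:05d}",
            sequence=_random_sequence(rng, length),
            abundance_fraction=float(others[i]),
            n_disulfides=n_ss,
            shielded_spans=_shield_spans(rng, length, n_ss, coverage),
        ))
    for g in range(params.n_giants):
        length = params.giant_length
        n_ss = int(rng.poisson(2.0))
        coverage = min(params.shield_coverage_per_disulfide * n_ss, 0.5)
        proteins.append(SimProtein(
            accession=f"GIANT{g:02d}",
            gene_symbol=f"GIANT{g:02d}",
            sequence=_random_sequence(rng, length),
            abundance_fraction=float(others[n_normal + g]),
            n_disulfides=n_ss,
            shielded_spans=_shield_spans(rng, length, n_ss, coverage),
            is_giant=True,
        ))
    total = sum(p.abundance_fraction for p in proteins)
    for p in proteins:
        p.abundance_fraction /= total
    return proteins


def database_dicts(
    proteins: Sequence[SimProtein],
    n_isoform_duplicates: int | None = None,
    params: SimParams | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """FASTA database + accession map, including historical-isoform duplicate
    accessions that share a gene symbol (to exercise symbol collapse)."""
    params = params or SimParams()
    if n_isoform_duplicates is None:
        n_isoform_duplicates = params.n_isoform_duplicates
    database = {p.accession: p.sequence for p in proteins}
    amap = {p.accession: p.gene_symbol for p in proteins}
    normal = [p for p in proteins if not (p.is_albumin or p.is_giant)]
    for p in normal[:n_isoform_duplicates]:
        dup = p.accession + ".2"
        database[dup] = p.sequence
        amap[dup] = p.gene_symbol
    return database, amap


def _digest_arrays(sequence: str, max_missed: int):
    """Vectorized tryptic fragment enumeration for one protein.

    Returns (starts, ends, mc, mass, n_frag) over all fragments with
    0..max_missed missed cleavages; mass is unmodified MH.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    cum = np.concatenate([[0.0], np.cumsum(_MASS_LUT[arr])])
    is_site = (arr == ord("K")) | (arr == ord("R"))
    sites = np.nonzero(is_site[:-1])[0]
    bounds = np.concatenate([[0], sites + 1, [len(arr)]])
    nfrag = len(bounds) - 1
    starts, ends, mcs = [], [], []
    for mc in range(max_missed + 1):
        if nfrag - mc <= 0:
            break
        starts.append(bounds[: nfrag - mc])
        ends.append(bounds[mc + 1:])
        mcs.append(np.full(nfrag - mc, mc))
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    mcs = np.concatenate(mcs)
    mass = cum[ends] - cum[starts] + WATER + PROTON
    return starts, ends, mcs, mass, nfrag


def build_peptide_pool(
    proteins: Sequence[SimProtein],
    params: SimParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Treatment-independent peptide pool: every tryptic peptide with its
    detectability factors.

    Columns: accession, gene_symbol, peptide, missed_cleavages, mh,
    shielded_frac, has_cys, base_factor (flyability x missed-cleavage penalty
    x mass detectability), abundance, n_frag (parent fragment count),
    is_albumin, is_giant.  ``seed`` fixes the per-peptide flyability draw, so
    the same seed yields the same pool for every treatment.
    """
    params = params or SimParams()
    rng = _child(seed, 1)
    frames = []
    for p in proteins:
        starts, ends, mcs, mass, nfrag = _digest_arrays(p.sequence, params.max_missed)
        shield = np.zeros(len(p.sequence) + 1)
        mask = np.zeros(len(p.sequence))
        for s, e in p.shielded_spans:
            mask[s:e] = 1.0
        shield[1:] = np.cumsum(mask)
        shielded_frac = (shield[ends] - shield[starts]) / (ends - starts)
        arr = np.frombuffer(p.sequence.encode("ascii"), dtype=np.uint8)
        cys = np.concatenate([[0], np.cumsum(arr == ord("C"))])
        has_cys = (cys[ends] - cys[starts]) > 0
        frames.append(pd.DataFrame({
            "accession": p.accession,
            "gene_symbol": p.gene_symbol,
            "start": starts,
            "end": ends,
            "missed_cleavages": mcs,
            "mh": mass,
            "shielded_frac": shielded_frac,
            "has_cys": has_cys,
            "abundance": p.abundance_fraction,
            "n_frag": nfrag,
            "is_albumin": p.is_albumin,
            "is_giant": p.is_giant,
        }))
    pool = pd.concat(frames, ignore_index=True)

    pen = np.asarray(params.missed_cleavage_penalty)
    penalty = pen[pool["missed_cleavages"].to_numpy()]
    mh = pool["mh"].to_numpy()
    lo, hi = params.mh_window
    detect = np.exp(
        -((np.log(mh) - np.log(params.detect_mh_center)) ** 2)
        / (2 * params.detect_mh_sigma ** 2)
    )
    detect[(mh < lo) | (mh > hi)] = 0.0
    fly = np.exp(rng.normal(0.0, params.flyability_sigma, size=len(pool)))
    pool["base_factor"] = fly * penalty * detect
    pool = pool[pool["base_factor"] > 0].reset_index(drop=True)

    seqs = {p.accession: p.sequence for p in proteins}
    pool["peptide"] = [
        seqs[a][s:e] for a, s, e in
        zip(pool["accession"], pool["start"], pool["end"])
    ]
    return pool.drop(columns=["start", "end"])


def simulate_treatment_digest(
    proteins: Sequence[SimProtein],
    treatment: str,
    params: SimParams | None = None,
    seed: int = 0,
    base_pool: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Peptide sampling distribution for one digestion treatment.

    Peptides inside disulfide-shielded spans carry their weight scaled by the
    treatment's reduction-release fraction; cysteine peptides are split into a
    CAM-modified and an unmodified entry with the treatment's CAM rate; each
    protein's released weight is normalized by its fully released detectable
    flux, so a protein's total sampling weight under full release equals its
    abundance fraction (competition then renormalizes across proteins).
    """
    params = params or SimParams()
    if treatment not in params.reduction_release:
        raise ValueError(f"unknown treatment {treatment!r}")
    pool = base_pool if base_pool is not None else build_peptide_pool(
        proteins, params, seed
    )
    release = params.reduction_release[treatment]
    cam_rate = params.cam_rate[treatment]

    factor = pool["base_factor"].to_numpy()
    shielded = pool["shielded_frac"].to_numpy()
    access = (1.0 - shielded) + shielded * release
    released = factor * access
    # normalize by each protein's fully released flux
    denom = pd.Series(factor).groupby(pool["accession"]).transform("sum").to_numpy()
    weight = pool["abundance"].to_numpy() * released / denom

    out = pool.copy()
    out["treatment"] = treatment
    out["cam"] = False
    out["weight"] = weight
    cysrows = out[out["has_cys"]].copy()
    if cam_rate > 0 and len(cysrows):
        cam = cysrows.copy()
        cam["cam"] = True
        cam["mh"] = cam["mh"] + _CAM_DELTA
        cam["weight"] = cysrows["weight"] * cam_rate
        out.loc[out["has_cys"], "weight"] *= (1.0 - cam_rate)
        out = pd.concat([out, cam], ignore_index=True)
    out = out[out["weight"] > 0].reset_index(drop=True)
    out["weight"] = out["weight"] / out["weight"].sum()
    out["mods"] = ""
    cam_mask = out["cam"].to_numpy()
    if cam_mask.any():
        pos = [s.find("C") + 1 for s in out.loc[cam_mask, "peptide"]]
        out.loc[cam_mask, "mods"] = [f"{p}:CAM" for p in pos]
    return out


def make_noise_pool(params: SimParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Background (blank-injection) peptide pool: polymer/contaminant-like
    sequences outside the protein database, with lognormal relative rates."""
    params = params or SimParams()
    rng = _child(seed, 2)
    n = params.noise_peptide_pool_size
    lengths = rng.integers(6, 25, size=n)
    # lowercase-free random sequences ending in K/R so they look tryptic
    seqs = [
        _random_sequence(rng, int(ln - 1)) + ("K" if rng.random() < 0.5 else "R")
        for ln in lengths
    ]
    mh = np.array([
        float(np.sum(_MASS_LUT[np.frombuffer(s.encode(), np.uint8)])) + WATER + PROTON
        for s in seqs
    ])
    w = np.exp(rng.normal(0, 1.0, size=n))
    return pd.DataFrame({
        "peptide": seqs, "mh": mh, "weight": w / w.sum(), "mods": "",
    })


def _decoy_distribution(pool: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row indices and probabilities for spurious (length-proportional)
    matches: unmodified 0-missed-cleavage peptides, probability proportional
    to the parent protein's tryptic fragment count."""
    unmodified = ~pool["cam"] if "cam" in pool.columns else True
    mask = (pool["missed_cleavages"] == 0) & unmodified
    idx = np.nonzero(mask.to_numpy())[0]
    p = pool.loc[mask, "n_frag"].to_numpy(dtype=float)
    return idx, p / p.sum()


def _xcorr_scores(rng, loc, scale, size):
    a = (0.0 - loc) / scale
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale,
                               size=size, random_state=rng)


def simulate_runs(
    pool: pd.DataFrame,
    design: TreatmentDesign,
    params: SimParams | None = None,
    seed: int = 0,
    noise_pool: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every run of one treatment for both engines.

    Each run allocates ``spectra_per_run`` spectra multinomially over the
    peptide pool weights (the ionization / cycle-time competition mechanism).
    A ``random_match_fraction`` of spectra are spurious matches drawn from the
    length-proportional decoy distribution, and a ``noise_fraction`` are
    contaminant spectra from the blank-noise pool.  Both engines score every
    spectrum; wrong or spurious assignments draw from the false score models.
    A ``multi_candidate_fraction`` of spectra also emit worse-scoring rank-2/3
    candidates to exercise best-fit-per-spectrum selection downstream.

    Returns ``(psms, truth)``: the PSM table (both engines, all ranks) and a
    per-spectrum ground-truth table (spectrum kind and source protein).
    """
    params = params or SimParams()
    if len(pool) == 0:
        raise ValueError("empty peptide pool")
    treatment = pool["treatment"].iloc[0]
    stream = {"T": 0, "DT": 1, "DAT": 2}.get(treatment, 9)
    rng = _child(seed, 3, stream)
    if noise_pool is None:
        noise_pool = make_noise_pool(params, seed)

    n_runs = design.runs_per_treatment
    n = params.spectra_per_run
    N = n_runs * n

    run_ids = np.repeat(
        np.array([f"{treatment}_r{k:03d}" for k in range(n_runs)]), n
    )
    scans = np.tile(np.arange(1, n + 1), n_runs)

    kinds = rng.choice(
        3, size=N,
        p=[1 - params.random_match_fraction - params.noise_fraction,
           params.random_match_fraction, params.noise_fraction],
    )  # 0 true, 1 random-spurious, 2 noise-contaminant
    true_ix = kinds == 0
    rand_ix = kinds == 1
    noise_ix = kinds == 2

    weights = pool["weight"].to_numpy()
    src_row = np.zeros(N, dtype=np.int64)
    src_row[true_ix] = rng.choice(len(pool), size=int(true_ix.sum()), p=weights)
    didx, dprob = _decoy_distribution(pool)
    src_row[rand_ix] = didx[
        rng.choice(len(didx), size=int(rand_ix.sum()), p=dprob)
    ]
    noise_row = rng.choice(
        len(noise_pool), size=int(noise_ix.sum()),
        p=noise_pool["weight"].to_numpy(),
    )

    pep = pool["peptide"].to_numpy(dtype=object)[src_row]
    mods = pool["mods"].to_numpy(dtype=object)[src_row]
    theo = pool["mh"].to_numpy()[src_row]
    acc = pool["accession"].to_numpy(dtype=object)[src_row]
    sym = pool["gene_symbol"].to_numpy(dtype=object)[src_row]
    pep[noise_ix] = noise_pool["peptide"].to_numpy(dtype=object)[noise_row]
    mods[noise_ix] = ""
    theo[noise_ix] = noise_pool["mh"].to_numpy()[noise_row]
    acc[noise_ix] = "NOISE"
    sym[noise_ix] = "NOISE"

    charge = np.where(rng.random(N) < params.p_charge2, 2, 3)
    intensity = np.exp(rng.normal(
        params.log_intensity_mean, params.log_intensity_sd, size=N
    ))
    iso = rng.choice(
        np.asarray(params.isotope_classes), size=N,
        p=np.asarray(params.isotope_class_probs),
    )
    jitter = np.clip(
        rng.normal(0, params.mass_jitter_sd, size=N),
        -params.mass_jitter_max, params.mass_jitter_max,
    )
    observed_mh = theo + iso * NEUTRON_SPACING + jitter

    spectra = pd.DataFrame({
        "run_id": run_ids, "scan": scans, "charge": charge,
        "precursor_mh": observed_mh, "intensity": intensity,
    })
    truth = pd.DataFrame({
        "run_id": run_ids, "scan": scans,
        "kind": np.choose(kinds, ["TRUE", "RANDOM", "NOISE"]),
        "peptide": pep, "accession": acc, "gene_symbol": sym,
        "treatment": treatment,
    })
    truth["spectrum_key"] = truth["run_id"] + ":" + truth["scan"].astype(str)

    a, b = params.gof_true_beta
    frames = []
    for engine in ("GOF", "XCORR"):
        correct = rng.random(N) < params.p_correct[engine]
        # noise contaminants are genuine matches for both engines
        is_true_match = (true_ix & correct) | noise_ix
        e_pep = pep.copy()
        e_mods = mods.copy()
        n_wrong = int((~is_true_match & ~rand_ix).sum())
        wrong_rows = didx[rng.choice(len(didx), size=n_wrong, p=dprob)]
        wrong_mask = ~is_true_match & ~rand_ix
        e_pep[wrong_mask] = pool["peptide"].to_numpy(dtype=object)[wrong_rows]
        e_mods[wrong_mask] = pool["mods"].to_numpy(dtype=object)[wrong_rows]

        if engine == "GOF":
            score = rng.uniform(1e-12, 1.0, size=N)
            nt = int(is_true_match.sum())
            score[is_true_match] = np.clip(
                rng.beta(a, b, size=nt), 1e-16, 1.0
            )
        else:
            score = _xcorr_scores(rng, *params.xcorr_false, N)
            nt = int(is_true_match.sum())
            score[is_true_match] = _xcorr_scores(rng, *params.xcorr_true, nt)

        base = spectra.copy()
        base["engine"] = engine
        base["peptide"] = e_pep
        base["mods"] = e_mods
        base["score"] = score
        base["rank"] = 1
        base["treatment"] = treatment
        frames.append(base)

        # worse-scoring extra candidates
        extra_mask = rng.random(N) < params.multi_candidate_fraction
        n_extra = int(extra_mask.sum())
        if n_extra:
            rows2 = didx[rng.choice(len(didx), size=n_extra, p=dprob)]
            extra = base.loc[extra_mask].copy()
            extra["peptide"] = pool["peptide"].to_numpy(dtype=object)[rows2]
            extra["mods"] = pool["mods"].to_numpy(dtype=object)[rows2]
            extra["rank"] = 2
            s1 = score[extra_mask]
            if engine == "GOF":
                extra["score"] = np.clip(
                    s1 + (1 - s1) * rng.uniform(0.05, 1.0, size=n_extra), None, 1.0
                )
            else:
                extra["score"] = s1 * rng.uniform(0.0, 0.95, size=n_extra)
            frames.append(extra)

    psms = pd.concat(frames, ignore_index=True)
    psms = psms[[
        "run_id", "scan", "engine", "peptide", "mods", "charge",
        "precursor_mh", "intensity", "score", "rank", "treatment",
    ]]
    return psms, truth


def generate_blank_runs(
    design: TreatmentDesign,
    params: SimParams | None = None,
    seed: int = 0,
    noise_pool: pd.DataFrame | None = None,
    contaminant_pool: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Blank (no-injection) runs: noise-pool peptides plus an optional
    carryover subset of genuine sample peptides."""
    params = params or SimParams()
    if design.n_blank_runs < 1:
        raise ValueError("n_blank_runs must be >= 1")
    rng = _child(seed, 4)
    if noise_pool is None:
        noise_pool = make_noise_pool(params, seed)
    n_runs = design.n_blank_runs
    n = params.blank_spectra_per_run
    N = n_runs * n

    run_ids = np.repeat(
        np.array([f"BLANK_r{k:03d}" for k in range(n_runs)]), n
    )
    scans = np.tile(np.arange(1, n + 1), n_runs)

    contam_frac = params.blank_contaminant_fraction if contaminant_pool is not None else 0.0
    is_contam = rng.random(N) < contam_frac
    rows = rng.choice(
        len(noise_pool), size=N, p=noise_pool["weight"].to_numpy()
    )
    pep = noise_pool["peptide"].to_numpy(dtype=object)[rows]
    mods = np.full(N, "", dtype=object)
    theo = noise_pool["mh"].to_numpy()[rows]
    if is_contam.any():
        cw = contaminant_pool["weight"].to_numpy()
        crows = rng.choice(len(contaminant_pool), size=int(is_contam.sum()),
                           p=cw / cw.sum())
        pep[is_contam] = contaminant_pool["peptide"].to_numpy(dtype=object)[crows]
        mods[is_contam] = contaminant_pool["mods"].to_numpy(dtype=object)[crows]
        theo[is_contam] = contaminant_pool["mh"].to_numpy()[crows]

    charge = np.where(rng.random(N) < params.p_charge2, 2, 3)
    intensity = np.exp(rng.normal(
        params.log_intensity_mean - 2.0, params.log_intensity_sd, size=N
    ))
    iso = rng.choice(np.asarray(params.isotope_classes), size=N,
                     p=np.asarray(params.isotope_class_probs))
    observed = theo + iso * NEUTRON_SPACING + np.clip(
        rng.normal(0, params.mass_jitter_sd, N),
        -params.mass_jitter_max, params.mass_jitter_max,
    )
    a, b = params.gof_true_beta
    frames = []
    for engine in ("GOF", "XCORR"):
        if engine == "GOF":
            score = np.clip(rng.beta(a, b, size=N), 1e-16, 1.0)
        else:
            score = _xcorr_scores(rng, *params.xcorr_true, N)
        frames.append(pd.DataFrame({
            "run_id": run_ids, "scan": scans, "engine": engine,
            "peptide": pep, "mods": mods, "charge": charge,
            "precursor_mh": observed, "intensity": intensity,
            "score": score, "rank": 1, "treatment": "BLANK",
        }))
    return pd.concat(frames, ignore_index=True)


def albumin_ratio_t_dat(
    params: SimParams | None = None,
    design: TreatmentDesign | None = None,
    seed: int = 0,
) -> float:
    """Simulated albumin spectral-count ratio, trypsin-alone vs fully
    reduced+alkylated digestion (the albumin-suppression readout)."""
    params = params or SimParams()
    design = design or TreatmentDesign()
    proteins = generate_database(params.n_proteins, params, seed)
    base = build_peptide_pool(proteins, params, seed)
    noise = make_noise_pool(params, seed)
    counts = {}
    for treatment in ("T", "DAT"):
        pool = simulate_treatment_digest(
            proteins, treatment, params, seed, base_pool=base
        )
        _, truth = simulate_runs(pool, design, params, seed, noise)
        counts[treatment] = int((truth["accession"] == "ALB-SIM").sum())
    return counts["T"] / counts["DAT"]


@dataclass
class RandomMatchTable:
    """Random-spectrum match frequencies at peptide and symbol level."""

    per_peptide: pd.DataFrame  # key, count
    per_symbol: pd.DataFrame  # key, count
    total: int


def generate_random_matches(
    pool: pd.DataFrame,
    n_random_spectra: int = 150_000,
    seed: int = 0,
) -> RandomMatchTable:
    """Monte Carlo null: assign random spectra to peptides with probability
    proportional to the parent protein's tryptic fragment count, so matches
    accumulate preferentially in giant proteins."""
    if n_random_spectra < 1000:
        raise ValueError("n_random_spectra must be >= 1000")
    rng = _child(seed, 5)
    didx, dprob = _decoy_distribution(pool)
    counts = rng.multinomial(n_random_spectra, dprob)
    nonzero = counts > 0
    per_peptide = pd.DataFrame({
        "key": pool["peptide"].to_numpy(dtype=object)[didx[nonzero]],
        "gene_symbol": pool["gene_symbol"].to_numpy(dtype=object)[didx[nonzero]],
        "count": counts[nonzero],
    })
    # a peptide string can occur under several rows (shared across accessions)
    per_symbol = (
        per_peptide.groupby("gene_symbol", as_index=False)["count"].sum()
        .rename(columns={"gene_symbol": "key"})
    )
    per_peptide = per_peptide.groupby("key", as_index=False)["count"].sum()
    per_peptide.attrs["total"] = n_random_spectra
    per_symbol.attrs["total"] = n_random_spectra
    return RandomMatchTable(
        per_peptide=per_peptide, per_symbol=per_symbol, total=n_random_spectra
    )
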