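"""Synthetic-study generator: database structure, treatment-dependent
digestion weights, run simulation, blank runs, and the random-match null."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trypstat import io as tio
from trypstat.simulate import (
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

from conftest import small_design, small_params

SEED = 5


@pytest.fixture(scope="module")
def params():
    return small_params()


@pytest.fixture(scope="module")
def proteins(params):
    return generate_database(params.n_proteins, params, seed=SEED)


@pytest.fixture(scope="module")
def base_pool(proteins, params):
    return build_peptide_pool(proteins, params, seed=SEED)


class TestDatabase:
    def test_determinism_byte_identical_fasta(self, params, tmp_path):
        paths = []
        for k in range(2):
            prot = generate_database(params.n_proteins, params, seed=SEED)
            db, _ = database_dicts(prot, params=params)
            path = tmp_path / f"db{k}.fasta"
            tio.write_fasta(db, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_albumin_analog(self, proteins, params):
        albumin = [p for p in proteins if p.is_albumin]
        assert len(albumin) == 1
        assert albumin[0].abundance_fraction == pytest.approx(0.5, abs=1e-9)
        assert albumin[0].n_disulfides == max(p.n_disulfides for p in proteins)

    def test_abundance_normalized(self, proteins):
        assert sum(p.abundance_fraction for p in proteins) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_giants_are_long_and_scarce(self, proteins):
        giants = [p for p in proteins if p.is_giant]
        normal = [p for p in proteins if not (p.is_giant or p.is_albumin)]
        median_len = np.median([len(p.sequence) for p in normal])
        assert all(len(p.sequence) >= 5 * median_len for p in giants)
        assert max(p.abundance_fraction for p in giants) < min(
            p.abundance_fraction for p in normal
        )

    def test_shielded_spans_in_bounds(self, proteins):
        for p in proteins:
            for s, e in p.shielded_spans:
                assert 0 <= s < e <= len(p.sequence)

    def test_too_few_proteins_rejected(self, params):
        with pytest.raises(ValueError):
            generate_database(5, params, seed=SEED)


class TestTreatmentDigest:
    def test_albumin_suppressed_without_reduction(self, proteins, params, base_pool):
        shares = {}
        for t in ("T", "DAT"):
            pool = simulate_treatment_digest(
                proteins, t, params, SEED, base_pool=base_pool
            )
            shares[t] = pool.loc[pool["is_albumin"], "weight"].sum()
        assert shares["T"] <= 0.5 * shares["DAT"]

    def test_identical_release_gives_identical_weights(self, proteins, params, base_pool):
        flat = dataclasses.replace(
            params,
            reduction_release={"T": 0.7, "DT": 0.7, "DAT": 0.7},
            cam_rate={"T": 0.2, "DT": 0.2, "DAT": 0.2},
        )
        pools = [
            simulate_treatment_digest(proteins, t, flat, SEED, base_pool=base_pool)
            for t in ("T", "DAT")
        ]
        np.testing.assert_allclose(
            pools[0]["weight"].to_numpy(), pools[1]["weight"].to_numpy()
        )

    def test_zero_cam_rate_gives_no_cam_peptides(self, proteins, params, base_pool):
        nocam = dataclasses.replace(
            params, cam_rate={"T": 0.0, "DT": 0.0, "DAT": 0.0}
        )
        pool = simulate_treatment_digest(
            proteins, "DAT", nocam, SEED, base_pool=base_pool
        )
        assert not pool["cam"].any()
        assert (pool["mods"] == "").all()

    def test_unknown_treatment_rejected(self, proteins, params):
        with pytest.raises(ValueError, match="unknown treatment"):
            simulate_treatment_digest(proteins, "XX", params, SEED)

    def test_weights_are_distribution(self, proteins, params, base_pool):
        pool = simulate_treatment_digest(
            proteins, "DT", params, SEED, base_pool=base_pool
        )
        assert pool["weight"].sum() == pytest.approx(1.0)
        assert (pool["weight"] > 0).all()


@pytest.fixture(scope="module")
def run_output(proteins, params, base_pool):
    design = small_design()
    pool = simulate_treatment_digest(
        proteins, "DAT", params, SEED, base_pool=base_pool
    )
    noise = make_noise_pool(params, SEED)
    return design, simulate_runs(pool, design, params, SEED, noise)


class TestRuns:
    def test_determinism(self, proteins, params, base_pool):
        design = small_design()
        pool = simulate_treatment_digest(
            proteins, "T", params, SEED, base_pool=base_pool
        )
        noise = make_noise_pool(params, SEED)
        a, _ = simulate_runs(pool, design, params, SEED, noise)
        b, _ = simulate_runs(pool, design, params, SEED, noise)
        pd.testing.assert_frame_equal(a, b)

    def test_spectrum_conservation_per_run(self, run_output, params):
        design, (psms, truth) = run_output
        per_run = truth.groupby("run_id").size()
        assert (per_run == params.spectra_per_run).all()
        assert len(per_run) == design.runs_per_treatment
        # every spectrum scored by both engines at rank 1
        rank1 = psms[psms["rank"] == 1]
        assert len(rank1) == 2 * len(truth)

    def test_albumin_share_matches_weights(self, proteins, params, base_pool):
        design = small_design()
        pool = simulate_treatment_digest(
            proteins, "DAT", params, SEED, base_pool=base_pool
        )
        _, truth = simulate_runs(
            pool, design, params, SEED, make_noise_pool(params, SEED)
        )
        w_alb = pool.loc[pool["is_albumin"], "weight"].sum()
        p_true = 1 - params.noise_fraction - params.random_match_fraction
        expected = w_alb * p_true
        n = len(truth)
        observed = (truth["accession"] == "ALB-SIM").mean()
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * sd + 1e-12

    def test_charge_fraction(self, run_output, params):
        _, (psms, _) = run_output
        rank1 = psms[(psms["engine"] == "GOF") & (psms["rank"] == 1)]
        frac2 = (rank1["charge"] == 2).mean()
        sd = np.sqrt(params.p_charge2 * (1 - params.p_charge2) / len(rank1))
        assert abs(frac2 - params.p_charge2) <= 3 * sd

    def test_dialect_valid(self, run_output):
        _, (psms, _) = run_output
        tio.validate_psm_table(psms)


class TestBlankRuns:
    def test_default_design_emits_29_runs(self, params):
        design = TreatmentDesign()
        blanks = generate_blank_runs(design, params, SEED)
        assert blanks["run_id"].nunique() == 29

    def test_zero_contaminant_blanks_disjoint_from_sample(
        self, proteins, params, base_pool
    ):
        design = small_design()
        pool = simulate_treatment_digest(
            proteins, "DAT", params, SEED, base_pool=base_pool
        )
        blanks = generate_blank_runs(
            design, params, SEED, contaminant_pool=None
        )
        assert not set(blanks["peptide"]) & set(pool["peptide"])

    def test_determinism(self, params):
        design = small_design()
        a = generate_blank_runs(design, params, SEED)
        b = generate_blank_runs(design, params, SEED)
        pd.testing.assert_frame_equal(a, b)


class TestRandomMatches:
    def test_counts_conserved(self, base_pool, proteins, params):
        pool = simulate_treatment_digest(
            proteins, "DAT", params, SEED, base_pool=base_pool
        )
        table = generate_random_matches(pool, 1000, SEED)
        assert table.per_peptide["count"].sum() == 1000
        assert table.per_symbol["count"].sum() == 1000
        assert table.total == 1000

    def test_minimum_size_enforced(self, base_pool):
        with pytest.raises(ValueError):
            generate_random_matches(base_pool, 10, SEED)

    def test_giant_accumulation(self, proteins, params, base_pool):
        pool = simulate_treatment_digest(
            proteins, "DAT", params, SEED, base_pool=base_pool
        )
        table = generate_random_matches(pool, 20000, SEED)
        counts = dict(zip(table.per_symbol["key"], table.per_symbol["count"]))
        giants = [p.gene_symbol for p in proteins if p.is_giant]
        normal = [
            p.gene_symbol for p in proteins if not (p.is_giant or p.is_albumin)
        ]
        giant_mean = np.mean([counts.get(s, 0) for s in giants])
        normal_mean = np.mean([counts.get(s, 0) for s in normal])
        assert giant_mean > normal_mean

    def test_multinomial_goodness_of_fit(self, proteins, params, base_pool):
        from trypstat.simulate import _decoy_distribution

        pool = simulate_treatment_digest(
            proteins, "DAT", params, SEED, base_pool=base_pool
        )
        didx, dprob = _decoy_distribution(pool)
        sym = pool["gene_symbol"].to_numpy()[didx]
        expected_frac = pd.Series(dprob).groupby(sym).sum()
        n = 20000
        table = generate_random_matches(pool, n, SEED)
        observed = (
            table.per_symbol.set_index("key")["count"]
            .reindex(expected_frac.index)
            .fillna(0)
        )
        expected = expected_frac * n
        keep = expected >= 5
        chi2, p = stats.chisquare(
            observed[keep], expected[keep] / expected[keep].sum() * observed[keep].sum()
        )
        assert p > 0.01


class TestShapeOnDefaults:
    """Distribution-shape contracts of the default study conditions."""

    def test_fig2_shapes(self, default_result):
        from trypstat.pipeline import distribution_summary

        rank1 = default_result.raw["GOF"]
        summary = distribution_summary(
            rank1[rank1["rank"] == 1], sample=20000, seed=1
        )
        assert summary["mh_fraction_1000_3000"] >= 0.60
        assert summary["isotope_012_fraction"] >= 0.90
        assert summary["ln_intensity_normality_p"] > 1e-4
        assert abs(summary["charge2_fraction"] - 0.56) < 0.01
        mc = summary["missed_cleavage_fractions"]
        assert mc[0] > mc[1] > mc.get(2, 0.0)
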