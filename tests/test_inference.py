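"""Protein inference: score thresholds, symbol rollup, Fisher aggregation,
and Benjamini-Hochberg q-values (with independent oracles)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from trypstat.inference import (
    Thresholds,
    aggregate_protein_p,
    apply_score_thresholds,
    bh_qvalues,
    digest_index,
    rollup,
    tier_report,
)


def _pool(rows):
    return pd.DataFrame(
        [
            dict(
                run_id="r0", scan=i, engine=e, peptide=p, mods="", charge=2,
                precursor_mh=800.0, intensity=1e4, score=s, rank=1,
                treatment="T",
            )
            for i, (e, p, s) in enumerate(rows)
        ]
    )


class TestScoreThresholds:
    def test_gof_boundary_inclusive(self):
        pool = _pool([("GOF", "AAK", 0.1), ("GOF", "CCK", 0.10001)])
        kept = apply_score_thresholds(pool)
        assert kept["peptide"].tolist() == ["AAK"]

    def test_xcorr_boundary(self):
        pool = _pool([("XCORR", "AAK", 2.0), ("XCORR", "CCK", 1.99)])
        kept = apply_score_thresholds(pool)
        assert kept["peptide"].tolist() == ["AAK"]

    def test_empty_pool(self):
        kept = apply_score_thresholds(_pool([]).reindex(columns=_pool([("GOF", "A", 0.5)]).columns))
        assert len(kept) == 0


class TestFisherAggregation:
    def test_single_p_identity(self):
        for p in (0.001, 0.1, 0.73, 1.0):
            assert aggregate_protein_p([p]) == pytest.approx(p, rel=1e-9)

    def test_two_equal_p(self):
        # -2 * (ln 0.1 + ln 0.1) = 9.2103 on 4 df
        assert aggregate_protein_p([0.1, 0.1]) == pytest.approx(0.0563, abs=5e-4)

    def test_p_of_one_contributes_nothing_to_statistic(self):
        base = -2 * np.log(0.05)
        with_one = aggregate_protein_p([0.05, 1.0])
        assert with_one == pytest.approx(stats.chi2.sf(base, df=4), rel=1e-9)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = rng.uniform(1e-6, 1, size=rng.integers(1, 8))
            expected = stats.combine_pvalues(ps, method="fisher").pvalue
            assert aggregate_protein_p(ps) == pytest.approx(expected, rel=1e-9)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            aggregate_protein_p([])
        with pytest.raises(ValueError):
            aggregate_protein_p([0.0])


def _bh_brute_force(p):
    """Literal step-up: q_(i) = min_{j>=i} (m/j) p_(j), in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(
            min((m / (j + 1)) * p[order[j]] for j in range(pos, m)), 1.0
        )
    return q


class TestBHQValues:
    def test_single_p(self):
        assert bh_qvalues([0.04])[0] == pytest.approx(0.04)

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_qvalues([0.2] * 5), [0.2] * 5)

    def test_brute_force_oracle_1000_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40)).tolist()
            np.testing.assert_allclose(
                bh_qvalues(p), _bh_brute_force(p), atol=1e-12
            )

    def test_statsmodels_cross_check(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=500)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_qvalues(p), expected, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, size=200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRollup:
    def test_unique_peptide_single_symbol(self):
        pool = _pool([("GOF", "MK", 0.01)])
        rollups, orphans = rollup(pool, {"MK": {"S1"}})
        assert len(rollups) == 1
        assert rollups.loc[0, "gene_symbol"] == "S1"
        assert rollups.loc[0, "n_peptides"] == 1
        assert len(orphans) == 0

    def test_accessions_sharing_symbol_collapse(self):
        database = {"A1": "MKGR", "A2": "MKSA"}
        amap = {"A1": "S1", "A2": "S1"}
        _, pep_to_sym = digest_index(database, amap, max_missed=0)
        pool = _pool([("GOF", "MK", 0.01), ("GOF", "GR", 0.02)])
        rollups, _ = rollup(pool, pep_to_sym)
        assert len(rollups) == 1
        assert rollups.loc[0, "n_peptides"] == 2

    def test_shared_peptide_counts_toward_each_symbol(self):
        pool = _pool([("GOF", "MK", 0.01)])
        rollups, _ = rollup(pool, {"MK": {"S1", "S2"}})
        assert sorted(rollups["gene_symbol"]) == ["S1", "S2"]
        assert (rollups["spectral_count"] == 1).all()

    def test_orphans_routed_not_dropped(self):
        pool = _pool([("GOF", "MK", 0.01), ("GOF", "ZZZZK", 0.02)])
        rollups, orphans = rollup(pool, {"MK": {"S1"}})
        assert orphans["key"].tolist() == ["ZZZZK"]
        assert len(rollups) == 1

    def test_spectral_count_conservation(self, small_result):
        accepted = small_result.accepted["GOF"]
        pep_to_sym = small_result.pep_to_sym
        mapped = accepted[accepted["peptide"].map(
            lambda p: p in pep_to_sym
        )]
        total = small_result.rollups["GOF"]["spectral_count"].sum()
        assert total >= len(mapped)


class TestTierReport:
    def test_empty(self):
        empty = pd.DataFrame(
            columns=["gene_symbol", "n_peptides", "spectral_count",
                     "p_protein", "q_value"]
        )
        report = tier_report(empty)
        assert (report["n_symbols"] == 0).all()

    def test_recount_oracle(self, small_result):
        rollups = small_result.rollups["GOF"]
        report = tier_report(rollups).set_index("min_peptides")
        for tier in (1, 2, 3):
            brute = sum(
                1 for _, r in rollups.iterrows() if r["n_peptides"] >= tier
            )
            brute_q = sum(
                1 for _, r in rollups.iterrows()
                if r["n_peptides"] >= tier and r["q_value"] <= 0.01
            )
            assert report.loc[tier, "n_symbols"] == brute
            assert report.loc[tier, "n_symbols_q_le_0.01"] == brute_q

    def test_union_tier_at_least_single_treatment(self, small_result):
        union = set(
            small_result.rollups["GOF"].query("n_peptides >= 2")["gene_symbol"]
        )
        for t in small_result.config.design.treatments:
            per_t = small_result.rollups_by_treatment[("GOF", t)]
            assert len(union) >= len(per_t.query("n_peptides >= 2"))
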