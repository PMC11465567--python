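"""Observation-frequency correction against blank and random controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trypstat.freqfilter import (
    chi_square_frequency,
    filter_against_control,
    peptide_counts,
    symbol_counts,
)


def _pool(peptide_counts_map: dict[str, int]) -> pd.DataFrame:
    rows = []
    scan = 0
    for pep, n in peptide_counts_map.items():
        for _ in range(n):
            scan += 1
            rows.append(
                dict(
                    run_id="r0", scan=scan, engine="GOF", peptide=pep,
                    mods="", charge=2, precursor_mh=800.0, intensity=1e4,
                    score=0.01, rank=1, treatment="T",
                )
            )
    return pd.DataFrame(rows)


def _control(counts: dict[str, int], total: int) -> pd.DataFrame:
    table = pd.DataFrame({"key": list(counts), "count": list(counts.values())})
    table.attrs["total"] = total
    return table


class TestChiSquare:
    def test_threshold_nine_gives_p_below_0p01(self):
        # chi-square of exactly 9 at 1 df
        p_at_9 = stats.chi2.sf(9, df=1)
        assert p_at_9 == pytest.approx(0.0027, abs=2e-4)
        assert p_at_9 <= 0.01
        # a count configuration that lands exactly at 9: obs = E + 3*sqrt(E)
        chi2, p = chi_square_frequency(160, 10000, 100, 10000)
        assert chi2 == pytest.approx(36.0)
        assert p == pytest.approx(stats.chi2.sf(36, 1), rel=1e-12)

    def test_count_matching_expectation_gives_zero(self):
        chi2, p = chi_square_frequency(50, 10000, 50, 10000)
        assert chi2 == 0.0
        assert p == 1.0

    def test_pseudocount_floor_for_absent_control(self):
        chi2, _ = chi_square_frequency(40, 10000, 0, 10000)
        # expectation floored at the pseudocount, so chi2 = (40-0.5)^2/0.5
        assert chi2 == pytest.approx((40 - 0.5) ** 2 / 0.5)
        assert chi2 >= 9

    def test_bad_totals_rejected(self):
        with pytest.raises(ValueError):
            chi_square_frequency(1, 0, 1, 10)
        with pytest.raises(ValueError):
            chi_square_frequency(-1, 10, 1, 10)


class TestFilterAgainstControl:
    def test_absent_from_control_retained(self):
        pool = _pool({"AAAK": 50})
        retained, decisions = filter_against_control(
            pool, _control({}, 1000)
        )
        assert len(retained) == 50
        assert decisions["reason"].tolist() == ["PASS"]

    def test_same_normalized_frequency_discarded(self):
        pool = _pool({"AAAK": 10, "CCCK": 90})
        retained, decisions = filter_against_control(
            pool, _control({"AAAK": 10, "CCCK": 90}, 100)
        )
        assert len(retained) == 0
        assert not decisions["retained"].any()

    def test_noise_enriched_peptide_discarded(self):
        # experimental rate far below the control rate: not resolved
        pool = _pool({"AAAK": 5, "GGGK": 500})
        retained, decisions = filter_against_control(
            pool, _control({"AAAK": 200}, 1000)
        )
        dec = decisions.set_index("key")
        assert not dec.loc["AAAK", "retained"]
        assert dec.loc["GGGK", "retained"]
        assert set(retained["peptide"]) == {"GGGK"}

    def test_hard_mode_discards_any_overlap(self):
        pool = _pool({"AAAK": 500, "GGGK": 5})
        retained, decisions = filter_against_control(
            pool, _control({"AAAK": 1}, 1000), mode="hard"
        )
        dec = decisions.set_index("key")
        assert dec.loc["AAAK", "reason"] == "HARD_BLANK_OVERLAP"
        assert set(retained["peptide"]) == {"GGGK"}

    def test_counts_conserved_and_idempotent(self):
        pool = _pool({"AAAK": 30, "CCCK": 3, "GGGK": 1})
        control = _control({"CCCK": 50}, 1000)
        retained, decisions = filter_against_control(pool, control)
        assert set(decisions["key"]) == set(pool["peptide"])
        kept_keys = set(decisions.loc[decisions["retained"], "key"])
        n_discarded_rows = int((~pool["peptide"].isin(kept_keys)).sum())
        assert len(retained) + n_discarded_rows == len(pool)
        again, _ = filter_against_control(retained, control)
        pd.testing.assert_frame_equal(again, retained)

    def test_retained_p_below_threshold_p(self):
        pool = _pool({"AAAK": 40, "CCCK": 12, "GGGK": 2})
        _, decisions = filter_against_control(pool, _control({}, 5000))
        p_threshold = stats.chi2.sf(9, df=1)
        retained = decisions[decisions["retained"]]
        assert (retained["p_value"] <= p_threshold).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            filter_against_control(_pool({"AAAK": 1}), _control({}, 10), mode="x")

    def test_symbol_level_filter(self):
        pool = _pool({"AAAK": 40, "CCCK": 40})
        pep_to_sym = {"AAAK": {"S1"}, "CCCK": {"S2"}}
        # S2's rate matches the control null; S1 absent from control
        control = _control({"S2": 400}, 800)
        retained, decisions = filter_against_control(
            pool, control, level="symbol", peptide_to_symbols=pep_to_sym,
            reason="NOT_RESOLVED_FROM_RANDOM",
        )
        dec = decisions.set_index("key")
        assert dec.loc["S1", "retained"]
        assert not dec.loc["S2", "retained"]
        assert dec.loc["S2", "reason"] == "NOT_RESOLVED_FROM_RANDOM"
        assert set(retained["peptide"]) == {"AAAK"}


class TestCountHelpers:
    def test_peptide_counts_total(self):
        counts = peptide_counts(_pool({"AAAK": 3, "CCCK": 2}))
        assert counts.attrs["total"] == 5
        assert dict(zip(counts["key"], counts["count"])) == {"AAAK": 3, "CCCK": 2}

    def test_symbol_counts_shared_peptide_counts_to_both(self):
        counts = symbol_counts(
            _pool({"AAAK": 4}), {"AAAK": {"S1", "S2"}}
        )
        got = dict(zip(counts["key"], counts["count"]))
        assert got == {"S1": 4, "S2": 4}


def test_blank_filter_removes_noise_pool_peptides(small_result):
    """On simulated data with known ground truth, >=95% of peptides that are
    only in the blank-noise pool are removed by the blank filter."""
    truth = small_result.truth
    noise_peps = set(truth.loc[truth["kind"] == "NOISE", "peptide"])
    true_peps = set(truth.loc[truth["kind"] != "NOISE", "peptide"])
    noise_only = noise_peps - true_peps
    consolidated = set(small_result.consolidated["GOF"].psms["peptide"])
    survived = set(small_result.noise_corrected["GOF"]["peptide"])
    present = noise_only & consolidated
    assert len(present) > 10
    assert len(present & survived) / len(present) <= 0.05
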