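"""Shared fixtures: a small fast simulation for unit tests and one
default-scale pipeline run shared by the acceptance-surface tests."""

from __future__ import annotations

import dataclasses

import pytest

from trypstat.pipeline import Config, run_pipeline
from trypstat.simulate import SimParams, TreatmentDesign


def small_params(**overrides) -> SimParams:
    base = dict(
        n_proteins=60,
        spectra_per_run=150,
        n_giants=5,
        giant_length=4000,
        n_isoform_duplicates=5,
        noise_peptide_pool_size=80,
        blank_spectra_per_run=80,
    )
    base.update(overrides)
    return SimParams(**base)


def small_design(**overrides) -> TreatmentDesign:
    base = dict(blocks=(2, 2), n_blank_runs=4, n_random_spectra=2000)
    base.update(overrides)
    return TreatmentDesign(**base)


@pytest.fixture(scope="session")
def small_config() -> Config:
    return Config(sim=small_params(), design=small_design())


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config, seed=7)


@pytest.fixture(scope="session")
def default_result():
    """One full default-scale study: the acceptance surface."""
    return run_pipeline(Config(), seed=11)
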