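"""Shared fixtures: the default breath preset and cheap reduced cohorts."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import breathgc as bg

settings.register_profile(
    "breathgc",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("breathgc")


@pytest.fixture(scope="session")
def default_profile() -> bg.SimulationProfile:
    return bg.default_breath_profile()


@pytest.fixture(scope="session")
def default_chrom(default_profile) -> bg.Chromatogram:
    chrom, _ = bg.simulate_chromatogram(default_profile, seed=0)
    return chrom


@pytest.fixture(scope="session")
def default_peaks(default_chrom) -> bg.PeakTable:
    return bg.detect_peaks(default_chrom)


@pytest.fixture(scope="session")
def default_study(default_profile):
    study, truth = bg.simulate_study(default_profile, seed=0)
    return bg.qc_filter(study, 5.0), truth


def make_small_profile(n_subjects: int = 3) -> bg.SimulationProfile:
    """A cheap cohort that still spans all three retention windows."""
    rng = np.random.default_rng(12345)
    n = 10
    peak_rt = np.sort(rng.uniform(1.0, 31.0, n))
    return bg.SimulationProfile(
        duration_min=32.0,
        dt_min=0.02,
        peak_rt=peak_rt,
        peak_height=rng.uniform(15000.0, 40000.0, n),
        peak_sigma=np.full(n, 0.1),
        baseline_level=2000.0,
        baseline_drift=30.0,
        noise_sd=300.0,
        n_subjects=n_subjects,
    )


@pytest.fixture()
def small_profile() -> bg.SimulationProfile:
    return make_small_profile()


@pytest.fixture()
def small_study(small_profile):
    study, truth = bg.simulate_study(small_profile, seed=1)
    return study, truth


@pytest.fixture()
def noiseless_profile(default_profile) -> bg.SimulationProfile:
    return dataclasses.replace(default_profile, noise_sd=0.0)
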