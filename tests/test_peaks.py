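"""Unit and property tests for the peak-detection primitives."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps

import breathgc as bg
from breathgc.peaks import _interp_rt

from .oracles import gaussian_area, local_maxima_oracle, prominence_oracle, width_oracle

int_signals = st.lists(st.integers(min_value=0, max_value=12), min_size=3, max_size=40)


# ---------------------------------------------------------------- local maxima


@pytest.mark.parametrize(
    "y, expected",
    [
        ([0, 1, 0], [1]),
        ([0, 1, 2, 3], []),
        ([3, 2, 1, 0], []),
        ([0, 2, 2, 2, 0], [2]),
        ([0, 2, 2, 0], [1]),
        ([0, 1, 0, 1, 0], [1, 3]),
        ([1, 1, 1, 1], []),
        ([0, 2, 2], []),  # plateau touching the edge never counts
        ([0, 1], []),  # too short for an interior maximum
    ],
)
def test_local_maxima_conventions(y, expected):
    assert bg.find_local_maxima(np.asarray(y, float)).tolist() == expected


@given(int_signals)
def test_local_maxima_match_plateau_enumeration(y):
    assert bg.find_local_maxima(np.asarray(y, float)).tolist() == local_maxima_oracle(y)


# ----------------------------------------------------------------- prominence


@pytest.mark.parametrize(
    "y, i, expected",
    [
        ([0, 5, 0], 1, (5.0, 0, 2)),
        ([1, 3, 2, 4, 1], 3, (3.0, 0, 4)),
        ([1, 3, 2, 4, 1], 1, (1.0, 0, 2)),
    ],
)
def test_prominence_examples(y, i, expected):
    assert bg.peak_prominence(np.asarray(y, float), i) == expected


@pytest.mark.parametrize("y, i", [([0, 1, 2], 1), ([0, 1, 0], 0), ([0, 1, 0], 2)])
def test_prominence_rejects_non_maxima(y, i):
    with pytest.raises(bg.ValidationError):
        bg.peak_prominence(np.asarray(y, float), i)


@given(int_signals)
def test_prominence_matches_contour_oracle(y):
    y = np.asarray(y, float)
    for i in bg.find_local_maxima(y):
        assert bg.peak_prominence(y, int(i)) == prominence_oracle(y, int(i))


def test_primitives_match_scipy_on_random_signals():
    """Prominences, bases and widths agree exactly with scipy.signal."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        y = rng.integers(0, 30, size=rng.integers(5, 80)).astype(float)
        ours = bg.find_local_maxima(y)
        theirs, _ = sps.find_peaks(y)
        assert ours.tolist() == theirs.tolist()
        if ours.size == 0:
            continue
        prom, lb, rb = zip(*(bg.peak_prominence(y, int(i)) for i in ours))
        s_prom, s_lb, s_rb = sps.peak_prominences(y, ours)
        np.testing.assert_array_equal(prom, s_prom)
        np.testing.assert_array_equal(lb, s_lb)
        np.testing.assert_array_equal(rb, s_rb)
        widths = [
            bg.peak_width(y, int(i), p, l, r, 0.5)
            for i, p, l, r in zip(ours, prom, lb, rb)
        ]
        s_w, s_h, s_lip, s_rip = sps.peak_widths(y, ours, rel_height=0.5)
        np.testing.assert_allclose([w[0] for w in widths], s_w, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose([w[1] for w in widths], s_lip, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose([w[2] for w in widths], s_rip, rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------------------- width


@pytest.mark.parametrize(
    "rel_height, expected_width, expected_ips",
    [
        (0.5, 2.0, (1.0, 3.0)),
        (0.0, 0.0, (2.0, 2.0)),
        (1.0, 4.0, (0.0, 4.0)),
    ],
)
def test_width_on_triangle(rel_height, expected_width, expected_ips):
    y = np.asarray([0, 2, 4, 2, 0], float)
    prom, lb, rb = bg.peak_prominence(y, 2)
    w, lip, rip, _ = bg.peak_width(y, 2, prom, lb, rb, rel_height)
    assert (w, lip, rip) == (expected_width, *expected_ips)


def test_width_rejects_bad_rel_height():
    y = np.asarray([0, 2, 0], float)
    with pytest.raises(ValueError):
        bg.peak_width(y, 1, 2.0, 0, 2, rel_height=1.5)


@given(int_signals)
def test_width_matches_crossing_oracle(y):
    y = np.asarray(y, float)
    for i in bg.find_local_maxima(y):
        prom, lb, rb = bg.peak_prominence(y, int(i))
        w, lip, rip, _ = bg.peak_width(y, int(i), prom, lb, rb, 0.5)
        ow, olip, orip = width_oracle(y, int(i), prom, lb, rb, 0.5)
        assert (w, lip, rip) == pytest.approx((ow, olip, orip), abs=1e-12)


# ----------------------------------------------------------------------- area


def test_area_triangle_and_degenerate():
    assert bg.peak_area([0, 4, 0], [0.0, 1.0, 2.0], 0, 2) == pytest.approx(4.0)
    assert bg.peak_area([3, 3, 3], [0.0, 1.0, 2.0], 0, 2) == 0.0


def test_area_matches_gaussian_closed_form():
    """A clean simulated Gaussian's chord-subtracted area hits h*sigma*sqrt(2pi)."""
    prof = bg.SimulationProfile(
        duration_min=20.0,
        dt_min=0.005,
        peak_rt=np.asarray([10.0]),
        peak_height=np.asarray([5000.0]),
        peak_sigma=np.asarray([0.05]),
        baseline_level=0.0,
        baseline_drift=0.0,
        noise_sd=0.0,
    )
    chrom, _ = bg.simulate_chromatogram(prof, 0)
    table = bg.detect_peaks(chrom, prominence_min=100.0, width_min=2.0)
    assert len(table) == 1
    assert table.df["area"].iloc[0] == pytest.approx(gaussian_area(5000.0, 0.05), rel=0.01)


# ------------------------------------------------------------------ detection


def test_detect_flat_signal_is_empty():
    chrom = bg.Chromatogram("flat", np.arange(50) * 0.01, np.full(50, 7.0))
    assert len(bg.detect_peaks(chrom)) == 0


def test_detect_single_strong_peak_hits_truth():
    """One injected peak far above both thresholds is found at its true apex."""
    dt = 0.005
    prof = bg.SimulationProfile(
        duration_min=20.0,
        dt_min=dt,
        peak_rt=np.asarray([10.0]),
        peak_height=np.asarray([30000.0]),  # prominence 10x the threshold
        peak_sigma=np.asarray([3 * 8 * dt / 2.355]),  # width 3x the threshold
        baseline_level=500.0,
        baseline_drift=0.0,
        noise_sd=0.0,
    )
    chrom, truth = bg.simulate_chromatogram(prof, 0)
    table = bg.detect_peaks(chrom)
    assert len(table) == 1
    assert abs(table.df["apex_rt_min"].iloc[0] - truth.peaks["rt_true"].iloc[0]) <= dt


def test_detect_rejects_non_positive_thresholds(default_chrom):
    with pytest.raises(ValueError):
        bg.detect_peaks(default_chrom, prominence_min=0.0)
    with pytest.raises(ValueError):
        bg.detect_peaks(default_chrom, width_min=-1.0)


def test_detect_records_parameters(default_peaks):
    assert default_peaks.params == {
        "prominence_min": 3000.0,
        "width_min": 8.0,
        "rel_height": 0.5,
    }
    rts = default_peaks.df["apex_rt_min"].to_numpy()
    assert np.all(np.diff(rts) > 0)


def _subsampled(chrom: bg.Chromatogram, step: int = 4) -> bg.Chromatogram:
    return bg.Chromatogram(chrom.sample_id, chrom.rt[::step], chrom.intensity[::step])


def test_detection_shift_invariance(default_chrom):
    """Adding a constant changes heights only; prominence/width/area persist."""
    chrom = _subsampled(default_chrom)
    shifted = bg.Chromatogram("s", chrom.rt, chrom.intensity + 12345.0)
    a = bg.detect_peaks(chrom, 3000, 2).df
    b = bg.detect_peaks(shifted, 3000, 2).df
    assert len(a) == len(b) > 10
    np.testing.assert_array_equal(a["apex_rt_min"], b["apex_rt_min"])
    np.testing.assert_allclose(b["height"], a["height"] + 12345.0, rtol=1e-12)
    for col in ("prominence", "width_samples", "area"):
        np.testing.assert_allclose(a[col], b[col], rtol=1e-9)


def test_detection_scale_equivariance(default_chrom):
    """Scaling by c>0 scales heights, prominences, areas; widths unchanged."""
    c = 2.5
    chrom = _subsampled(default_chrom)
    scaled = bg.Chromatogram("c", chrom.rt, chrom.intensity * c)
    a = bg.detect_peaks(chrom, 3000, 2).df
    b = bg.detect_peaks(scaled, 3000 * c, 2).df
    assert len(a) == len(b) > 10
    for col in ("height", "prominence", "area"):
        np.testing.assert_allclose(b[col], a[col] * c, rtol=1e-9)
    np.testing.assert_allclose(b["width_samples"], a["width_samples"], rtol=1e-9)


def test_detection_monotone_in_thresholds(default_chrom):
    """Raising either threshold never yields more peaks."""
    base = len(bg.detect_peaks(default_chrom, 3000, 8))
    for prom in (3000, 6000, 10000, 20000):
        for width in (8, 12, 20):
            n = len(bg.detect_peaks(default_chrom, prom, width))
            assert n <= base
            base_prom = len(bg.detect_peaks(default_chrom, prom, 8))
            assert n <= base_prom


# ------------------------------------------------------------- estimator API


def test_peak_detector_sklearn_protocol(default_chrom):
    from sklearn.base import clone

    det = bg.PeakDetector(prominence_min=5000.0)
    assert det.get_params()["prominence_min"] == 5000.0
    det2 = clone(det).set_params(width_min=10.0)
    det2.fit(default_chrom)
    assert det2.n_peaks_ == len(det2.peak_table_) == len(det2.peaks_)
    assert det2.n_peaks_ > 0


def test_interp_rt_fractional_index():
    rt = np.asarray([0.0, 1.0, 2.0])
    assert _interp_rt(rt, 0.5) == pytest.approx(0.5)
    assert _interp_rt(rt, 2.0) == pytest.approx(2.0)
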