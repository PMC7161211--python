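"""Signal conditioning and quality control.

Two operations: low-pass filtering by a centred moving average with a
*shrink* edge rule (the averaging window is truncated to the part that
overlaps the signal, so output length equals input length and a constant
signal is a fixed point), and a robust signal-to-noise estimate used to
flag failed measurements.

The SNR estimator is

    SNR = (p95(y) − median(y)) / noise_sd,
    noise_sd = 1.4826 · median(|Δy|) / √2,

i.e. signal magnitude is the 95th-percentile excess over the median and the
noise scale is the MAD of first differences rescaled to a Gaussian standard
deviation (the √2 undoes the variance doubling of differencing). Both parts
are shift-invariant and scale in proportion, so the ratio is shift- and
scale-invariant; it requires no peak detection. A noiseless signal gets
SNR = +inf and always passes QC.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import Chromatogram, StudySet

DEFAULT_FILTER_WINDOW = 301
DEFAULT_SNR_THRESHOLD = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Moving-average parameters: odd window length in samples."""

    window: int = DEFAULT_FILTER_WINDOW
    edge_rule: str = "shrink"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd positive integer, got {self.window}")
        if self.edge_rule != "shrink":
            raise ValueError("only the 'shrink' edge rule is supported")


class MovingAverageSmoother(BaseEstimator, TransformerMixin):
    """Centred moving average, sklearn transformer style.

    ``transform`` accepts a 1-D signal or a 2-D array of row signals and
    returns the smoothed array of the same shape. Window 1 is the identity.
    The transform is linear, so it commutes with averaging across samples.
    """

    def __init__(self, window: int = DEFAULT_FILTER_WINDOW) -> None:
        self.window = window

    def fit(self, X: np.ndarray, y: None = None) -> "MovingAverageSmoother":
        FilterSpec(window=self.window)  # validates
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        FilterSpec(window=self.window)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return self._smooth(X)
        return np.vstack([self._smooth(row) for row in X])

    def _smooth(self, y: np.ndarray) -> np.ndarray:
        w = self.window
        if w == 1:
            return y.copy()
        kernel = np.ones(w)
        sums = np.convolve(y, kernel, mode="same")
        counts = np.convolve(np.ones(y.size), kernel, mode="same")
        return sums / counts


def moving_average(y: np.ndarray, spec: FilterSpec | int) -> np.ndarray:
    """Moving average of ``y`` under the shrink edge rule."""
    window = spec.window if isinstance(spec, FilterSpec) else int(spec)
    return MovingAverageSmoother(window=window).fit(y).transform(np.asarray(y, dtype=float))


class SNRQualityFilter(BaseEstimator):
    """Flag low signal-to-noise measurements, sklearn estimator style.

    ``score_samples`` returns the SNR of each row signal; ``predict``
    returns a boolean pass mask at the configured threshold.
    """

    def __init__(self, threshold: float = DEFAULT_SNR_THRESHOLD) -> None:
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: None = None) -> "SNRQualityFilter":
        return self

    @staticmethod
    def _snr(y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        noise_sd = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
        if noise_sd == 0.0:
            return float("inf")
        return float((np.percentile(y, 95) - np.median(y)) / noise_sd)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return np.asarray([self._snr(X)])
        return np.asarray([self._snr(row) for row in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.score_samples(X) >= self.threshold


def estimate_snr(chrom: Chromatogram) -> float:
    """Robust signal-to-noise ratio of one chromatogram (+inf if noiseless)."""
    return SNRQualityFilter._snr(chrom.intensity)


def qc_filter(study: StudySet, snr_threshold: float = DEFAULT_SNR_THRESHOLD) -> StudySet:
    """Flag samples whose SNR falls below ``snr_threshold``.

    No sample is removed: failing samples get ``qc_pass=False`` with reason
    ``"low SNR (<value>)"`` and downstream stages skip them.
    """
    flags: list[tuple[bool, str]] = []
    for s in study:
        snr = estimate_snr(s.chromatogram)
        if snr < snr_threshold:
            flags.append((False, f"low SNR ({snr:.3g})"))
        else:
            flags.append((True, ""))
    return study.with_flags(flags)
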