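"""From-scratch 1-D peak detection and the five per-peak features.

The detector works directly on the sampled total-ion signal. A *peak* is an
interior local maximum (plateaus count once, at their middle sample). Its
**topographic prominence** is its height above the highest saddle separating
it from higher ground: scanning outward from the apex on each side until a
strictly higher sample (or the signal edge), the lowest sample encountered
is that side's base, and prominence is apex height minus the higher of the
two base values. **Width** is measured at ``apex − rel_height · prominence``
by linear interpolation between samples, reported both in samples and in
minutes. **Area** is the trapezoidal integral between the two bases minus
the chord joining them (so area is invariant to adding a constant), clipped
at zero.

Detection keeps every local maximum with prominence >= ``prominence_min``
and width >= ``width_min`` samples; the defaults (3000 intensity units,
8 samples, half-prominence height) are the operating point at which a breath
chromatogram yields on the order of 100–150 peaks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import Chromatogram, ValidationError

DEFAULT_PROMINENCE_MIN = 3000.0
DEFAULT_WIDTH_MIN = 8.0
DEFAULT_REL_HEIGHT = 0.5


@dataclass
class Peak:
    """Features of one detected peak (indices refer to the sample grid)."""

    apex_index: int
    apex_rt: float
    height: float
    prominence: float
    left_base: int
    right_base: int
    width_samples: float
    width_min: float
    left_ip: float
    right_ip: float
    area: float


@dataclass
class PeakTable:
    """Per-sample peak collection plus the detection parameters that made it."""

    sample_id: str
    df: pd.DataFrame
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df) > 1:
            rts = self.df["apex_rt_min"].to_numpy()
            if np.any(np.diff(rts) <= 0):
                raise ValidationError("peak apex retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_peaks(self) -> int:
        return len(self.df)


def find_local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima of ``y``.

    A sample ``i`` qualifies when ``y[i-1] < y[i] > y[i+1]``; a flat-topped
    plateau strictly above both neighbours counts once, at its middle sample
    (the lower middle for even-length plateaus). Signal endpoints are never
    returned; signals shorter than 3 samples have no maxima.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    out: list[int] = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=np.intp)


def _check_local_maximum(y: np.ndarray, i: int) -> None:
    n = y.size
    if not (0 < i < n - 1):
        raise ValidationError(f"index {i} is not an interior sample")
    j = i
    while j > 0 and y[j - 1] == y[i]:
        j -= 1
    k = i
    while k < n - 1 and y[k + 1] == y[i]:
        k += 1
    if j == 0 or k == n - 1 or y[j - 1] >= y[i] or y[k + 1] >= y[i]:
        raise ValidationError(f"index {i} is not a local maximum")


def peak_prominence(y: np.ndarray, i: int) -> tuple[float, int, int]:
    """Topographic prominence of the local maximum at ``i``.

    Returns ``(prominence, left_base, right_base)``. Each base is the lowest
    sample between the apex and the nearest strictly higher sample on that
    side (or the signal edge); ties go to the sample nearest the apex.
    """
    y = np.asarray(y, dtype=float)
    _check_local_maximum(y, i)

    left_min = y[i]
    left_base = i
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        if y[j] < left_min:
            left_min = y[j]
            left_base = j
        j -= 1

    right_min = y[i]
    right_base = i
    j = i + 1
    while j < y.size and y[j] <= y[i]:
        if y[j] < right_min:
            right_min = y[j]
            right_base = j
        j += 1

    prominence = float(y[i] - max(left_min, right_min))
    return prominence, int(left_base), int(right_base)


def peak_width(
    y: np.ndarray,
    i: int,
    prominence: float,
    left_base: int,
    right_base: int,
    rel_height: float = DEFAULT_REL_HEIGHT,
) -> tuple[float, float, float, float]:
    """Peak width at ``y[i] - rel_height * prominence``.

    Returns ``(width_samples, left_ip, right_ip, eval_height)`` where the
    interpolation points are fractional sample indices of the crossings
    nearest the apex on either side (clamped at the prominence bases).
    """
    if not 0.0 <= rel_height <= 1.0:
        raise ValueError(f"rel_height must be in [0, 1], got {rel_height}")
    y = np.asarray(y, dtype=float)
    eval_height = float(y[i] - rel_height * prominence)

    j = i
    while j > left_base and y[j] > eval_height:
        j -= 1
    left_ip = float(j)
    if y[j] < eval_height:
        left_ip += (eval_height - y[j]) / (y[j + 1] - y[j])

    j = i
    while j < right_base and y[j] > eval_height:
        j += 1
    right_ip = float(j)
    if y[j] < eval_height:
        right_ip -= (eval_height - y[j]) / (y[j - 1] - y[j])

    return right_ip - left_ip, left_ip, right_ip, eval_height


def peak_area(y: np.ndarray, rt: np.ndarray, left_base: int, right_base: int) -> float:
    """Chord-subtracted trapezoidal area between the prominence bases.

    The straight chord joining ``(rt[left_base], y[left_base])`` and
    ``(rt[right_base], y[right_base])`` acts as the local baseline, making
    the area invariant to adding a constant to the signal. Units are
    intensity × minutes; clipped below at zero.
    """
    y = np.asarray(y, dtype=float)
    rt = np.asarray(rt, dtype=float)
    seg_y = y[left_base : right_base + 1]
    seg_t = rt[left_base : right_base + 1]
    raw = np.trapezoid(seg_y, seg_t)
    chord = 0.5 * (y[left_base] + y[right_base]) * (rt[right_base] - rt[left_base])
    return float(max(raw - chord, 0.0))


def _interp_rt(rt: np.ndarray, frac_index: float) -> float:
    lo = int(np.floor(frac_index))
    hi = min(lo + 1, rt.size - 1)
    w = frac_index - lo
    return float(rt[lo] * (1.0 - w) + rt[hi] * w)


class PeakDetector(BaseEstimator):
    """Detect peaks in one chromatogram and compute their features.

    Follows the scikit-learn estimator protocol: parameters are set at
    construction, :meth:`fit` runs the detection and exposes the results as
    trailing-underscore attributes.

    Parameters
    ----------
    prominence_min : float
        Minimum topographic prominence, intensity units. Default 3000.
    width_min : float
        Minimum width in samples at the measurement height. Default 8.
    rel_height : float
        Fraction of the prominence below the apex at which width is
        measured. Default 0.5 (width at half prominence).

    Attributes
    ----------
    peaks_ : list of Peak
    peak_table_ : PeakTable
    n_peaks_ : int
    """

    def __init__(
        self,
        prominence_min: float = DEFAULT_PROMINENCE_MIN,
        width_min: float = DEFAULT_WIDTH_MIN,
        rel_height: float = DEFAULT_REL_HEIGHT,
    ) -> None:
        self.prominence_min = prominence_min
        self.width_min = width_min
        self.rel_height = rel_height

    def fit(self, X: Chromatogram, y: None = None) -> "PeakDetector":
        """Run detection on a chromatogram; returns self."""
        if self.prominence_min <= 0 or self.width_min <= 0:
            raise ValueError("prominence_min and width_min must be positive")
        if not 0.0 <= self.rel_height <= 1.0:
            raise ValueError("rel_height must be in [0, 1]")
        chrom = X
        sig = chrom.intensity
        rt = chrom.rt

        peaks: list[Peak] = []
        for idx in find_local_maxima(sig):
            prom, lb, rb = peak_prominence(sig, int(idx))
            if prom < self.prominence_min:
                continue
            w, lip, rip, _ = peak_width(sig, int(idx), prom, lb, rb, self.rel_height)
            if w < self.width_min:
                continue
            peaks.append(
                Peak(
                    apex_index=int(idx),
                    apex_rt=float(rt[idx]),
                    height=float(sig[idx]),
                    prominence=prom,
                    left_base=lb,
                    right_base=rb,
                    width_samples=w,
                    width_min=_interp_rt(rt, rip) - _interp_rt(rt, lip),
                    left_ip=lip,
                    right_ip=rip,
                    area=peak_area(sig, rt, lb, rb),
                )
            )
        peaks.sort(key=lambda p: p.apex_rt)

        df = pd.DataFrame(
            {
                "sample_id": [chrom.sample_id] * len(peaks),
                "apex_rt_min": [p.apex_rt for p in peaks],
                "height": [p.height for p in peaks],
                "prominence": [p.prominence for p in peaks],
                "width_samples": [p.width_samples for p in peaks],
                "width_min": [p.width_min for p in peaks],
                "area": [p.area for p in peaks],
                "left_base_rt": [float(rt[p.left_base]) for p in peaks],
                "right_base_rt": [float(rt[p.right_base]) for p in peaks],
                "apex_index": [p.apex_index for p in peaks],
                "left_ip": [p.left_ip for p in peaks],
                "right_ip": [p.right_ip for p in peaks],
            }
        )
        self.peaks_ = peaks
        self.peak_table_ = PeakTable(
            sample_id=chrom.sample_id,
            df=df,
            params={
                "prominence_min": float(self.prominence_min),
                "width_min": float(self.width_min),
                "rel_height": float(self.rel_height),
            },
        )
        self.n_peaks_ = len(peaks)
        return self


def detect_peaks(
    chrom: Chromatogram,
    prominence_min: float = DEFAULT_PROMINENCE_MIN,
    width_min: float = DEFAULT_WIDTH_MIN,
    rel_height: float = DEFAULT_REL_HEIGHT,
) -> PeakTable:
    """Detect peaks in ``chrom``; thin wrapper over :class:`PeakDetector`."""
    det = PeakDetector(
        prominence_min=prominence_min, width_min=width_min, rel_height=rel_height
    )
    return det.fit(chrom).peak_table_
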