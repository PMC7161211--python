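"""Condition-wise mean signals and retention-window summaries.

All QC-passing chromatograms are linearly interpolated onto a common
retention-time grid (spanning only the region every sample covers, stepped
at the median sampling interval), averaged per condition both raw and after
per-sample moving-average filtering, and summarised in three retention
windows: readily volatile compounds elute early (0–4 min), semi-volatile
compounds mid-run (16–19 min) and hardly volatile compounds late
(beyond 30 min). The per-window *baseline* estimate is the 10th percentile
of the mean signal inside the window — a low quantile is robust to the
peaks riding on top of it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .prep import DEFAULT_FILTER_WINDOW, FilterSpec, moving_average
from .types import Chromatogram, CONDITIONS, StudySet, ValidationError

BASELINE_QUANTILE = 10.0  # percentile used as the within-window baseline

#: Difference curves reported by compare_groups, minuend-subtrahend order.
DIFF_PAIRS = (("B", "A"), ("C", "A"), ("B", "C"))


@dataclass(frozen=True)
class Window:
    """A retention-time interval with explicit endpoint closure."""

    lo: float
    hi: float
    closed: str = "both"  # 'left' | 'right' | 'both' | 'neither'

    def __post_init__(self) -> None:
        if self.closed not in ("left", "right", "both", "neither"):
            raise ValueError(f"bad closure {self.closed!r}")
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")

    def mask(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        left = t >= self.lo if self.closed in ("left", "both") else t > self.lo
        right = t <= self.hi if self.closed in ("right", "both") else t < self.hi
        return left & right

    def contains(self, x: float) -> bool:
        return bool(self.mask(np.asarray([x]))[0])


def default_windows() -> dict[str, Window]:
    """The three retention windows of interest.

    W_early = [0, 4) min (readily volatile), W_mid = [16, 19] min
    (semi-volatile), W_late = (30, end] min (hardly volatile).
    """
    return {
        "W_early": Window(0.0, 4.0, closed="left"),
        "W_mid": Window(16.0, 19.0, closed="both"),
        "W_late": Window(30.0, math.inf, closed="right"),
    }


def common_grid(study: StudySet) -> np.ndarray:
    """Common retention-time grid over the QC-passing samples.

    Runs from the latest start to the earliest end among samples (so no
    sample is extrapolated), stepped at the median per-sample median
    sampling interval.
    """
    samples = study.passing()
    if not samples:
        raise ValidationError("no QC-passing samples in study")
    start = max(s.chromatogram.rt[0] for s in samples)
    end = min(s.chromatogram.rt[-1] for s in samples)
    if end <= start:
        raise ValidationError("samples have no common retention-time span")
    dt = float(np.median([s.chromatogram.dt for s in samples]))
    n = int(np.floor((end - start) / dt + 1e-9)) + 1
    return start + dt * np.arange(n)


def resample_to_grid(chrom: Chromatogram, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of the intensity onto ``grid``.

    Grid points outside the chromatogram's span become 0 and raise a
    warning counting them; an empty overlap is an error.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.max() < chrom.rt[0] or grid.min() > chrom.rt[-1]:
        raise ValidationError(
            f"grid does not overlap chromatogram {chrom.sample_id!r} "
            f"([{chrom.rt[0]:g}, {chrom.rt[-1]:g}] min)"
        )
    outside = int(np.sum((grid < chrom.rt[0]) | (grid > chrom.rt[-1])))
    if outside:
        warnings.warn(
            f"{outside} grid point(s) outside {chrom.sample_id!r}; set to 0",
            stacklevel=2,
        )
    return np.interp(grid, chrom.rt, chrom.intensity, left=0.0, right=0.0)


def group_mean(
    study: StudySet,
    condition: str,
    filter: FilterSpec | None = None,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise mean of the condition's QC-passing signals on the common grid.

    With ``filter`` given, each sample is moving-average filtered after
    resampling and before averaging (by linearity the order relative to the
    mean does not matter; per-sample filtering matches how per-sample
    artifacts are produced).
    """
    samples = study.passing(condition)
    if not samples:
        raise ValidationError(f"no QC-passing samples in condition {condition!r}")
    if grid is None:
        grid = common_grid(study)
    acc = np.zeros(grid.size)
    for s in samples:
        sig = resample_to_grid(s.chromatogram, grid)
        if filter is not None:
            sig = moving_average(sig, filter)
        acc += sig
    return acc / len(samples)


def windowed_summary(
    signal: np.ndarray,
    grid: np.ndarray,
    windows: dict[str, Window] | None = None,
) -> dict[str, dict[str, float]]:
    """Mean intensity and baseline estimate of ``signal`` per retention window.

    The baseline estimate is the 10th percentile of the signal within the
    window. A window with no grid point inside is an error.
    """
    if windows is None:
        windows = default_windows()
    signal = np.asarray(signal, dtype=float)
    out: dict[str, dict[str, float]] = {}
    for name, win in windows.items():
        m = win.mask(grid)
        if not m.any():
            raise ValidationError(f"window {name} contains no grid points")
        seg = signal[m]
        out[name] = {
            "mean": float(seg.mean()),
            "baseline": float(np.percentile(seg, BASELINE_QUANTILE)),
        }
    return out


@dataclass
class GroupSummary:
    """Per-condition mean signals and windowed statistics on a common grid."""

    grid: np.ndarray
    mean_raw: dict[str, np.ndarray]
    mean_filtered: dict[str, np.ndarray]
    n_samples: dict[str, int]
    window_stats: pd.DataFrame  # columns: condition, window, mean, baseline, n
    diff_curves: dict[str, np.ndarray]
    windows: dict[str, Window] = field(default_factory=default_windows)

    def validate_consistency(self) -> None:
        """Window stats must be recomputable from the filtered mean signals."""
        for _, row in self.window_stats.iterrows():
            recomputed = windowed_summary(
                self.mean_filtered[row["condition"]], self.grid, self.windows
            )[row["window"]]
            if not (
                np.isclose(recomputed["mean"], row["mean"], rtol=1e-12)
                and np.isclose(recomputed["baseline"], row["baseline"], rtol=1e-12)
            ):
                raise ValidationError(
                    f"window_stats inconsistent for {row['condition']}/{row['window']}"
                )


class GroupMeanComparator(BaseEstimator):
    """Compare condition-wise mean signals, sklearn estimator style.

    ``fit`` consumes a :class:`StudySet` (QC flags already applied) and
    exposes the resulting :class:`GroupSummary` as ``summary_``.

    Parameters
    ----------
    filter_window : int
        Moving-average window (samples) for the filtered means.
    """

    def __init__(self, filter_window: int = DEFAULT_FILTER_WINDOW) -> None:
        self.filter_window = filter_window

    def fit(self, X: StudySet, y: None = None) -> "GroupMeanComparator":
        study = X
        grid = common_grid(study)
        windows = default_windows()
        spec = FilterSpec(window=self.filter_window)

        mean_raw: dict[str, np.ndarray] = {}
        mean_filtered: dict[str, np.ndarray] = {}
        n_samples: dict[str, int] = {}
        rows: list[dict[str, object]] = []
        for cond in CONDITIONS:
            mean_raw[cond] = group_mean(study, cond, filter=None, grid=grid)
            mean_filtered[cond] = group_mean(study, cond, filter=spec, grid=grid)
            n_samples[cond] = len(study.passing(cond))
            for wname, stats in windowed_summary(mean_filtered[cond], grid, windows).items():
                rows.append(
                    {
                        "condition": cond,
                        "window": wname,
                        "mean": stats["mean"],
                        "baseline": stats["baseline"],
                        "n": n_samples[cond],
                    }
                )

        diffs = {
            f"{a}-{b}": mean_filtered[a] - mean_filtered[b] for a, b in DIFF_PAIRS
        }
        self.summary_ = GroupSummary(
            grid=grid,
            mean_raw=mean_raw,
            mean_filtered=mean_filtered,
            n_samples=n_samples,
            window_stats=pd.DataFrame(rows),
            diff_curves=diffs,
            windows=windows,
        )
        self.summary_.validate_consistency()
        return self


def compare_groups(
    study: StudySet, filter_window: int = DEFAULT_FILTER_WINDOW
) -> GroupSummary:
    """Full group comparison; thin wrapper over :class:`GroupMeanComparator`."""
    return GroupMeanComparator(filter_window=filter_window).fit(study).summary_


def write_group_summary(summary: GroupSummary, out_dir) -> None:
    """Write plot-ready CSVs: windowed stats and pairwise difference curves."""
    from pathlib import Path

    out = Path(out_dir)
    summary.window_stats.to_csv(out / "group_summary.csv", index=False, float_format="%.12g")
    diff = pd.DataFrame({"rt_min": summary.grid})
    for name, curve in summary.diff_curves.items():
        diff[name] = curve
    diff.to_csv(out / "diff_curves.csv", index=False, float_format="%.12g")
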