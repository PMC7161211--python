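"""Core domain containers for breath GC-MS studies.

A :class:`Chromatogram` is one breath sample's total-ion signal: paired
retention-time (minutes) and absolute-intensity series plus free-form header
metadata. A :class:`StudySample` tags a chromatogram with its subject and
sampling condition (A = before exposure, B = immediately after, C = 2 h
after), and a :class:`StudySet` is the full repeated-measures cohort with
per-sample QC status.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

#: Valid sampling conditions: before (A), immediately after (B), 2 h after (C).
CONDITIONS = ("A", "B", "C")


class ValidationError(ValueError):
    """A domain invariant is violated (monotonicity, uniqueness, ranges)."""


class ParseError(ValueError):
    """A text input could not be parsed; the message names line/row/column."""


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""


@dataclass
class Chromatogram:
    """One sample's signal: intensity versus retention time.

    Parameters
    ----------
    sample_id : str
        Opaque identifier for the measurement.
    rt : array-like of float
        Retention times in minutes, strictly increasing, length >= 2.
    intensity : array-like of float
        Absolute detector intensities (instrument units; the source figures
        label these mV), same length as ``rt``, all finite.
    relative_intensity : array-like of float, optional
        Intensity as percent of the sample maximum, in [0, 100]. Carried for
        round-tripping only; never used in computation (it is recomputable).
    meta : dict of str to str
        Key/value pairs parsed from file header lines.
    """

    sample_id: str
    rt: np.ndarray
    intensity: np.ndarray
    relative_intensity: np.ndarray | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.relative_intensity is not None:
            self.relative_intensity = np.asarray(self.relative_intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("rt and intensity must be 1-D series")
        if self.rt.size != self.intensity.size:
            raise ValidationError(
                f"rt and intensity lengths differ: {self.rt.size} vs {self.intensity.size}"
            )
        if self.rt.size < 2:
            raise ValidationError("empty signal: need at least 2 data points")
        if not np.all(np.isfinite(self.rt)):
            raise ValidationError("non-finite retention time")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite intensity")
        d = np.diff(self.rt)
        if np.any(d <= 0):
            k = int(np.argmax(d <= 0)) + 1  # first offending row (0-based)
            raise ValidationError(
                f"retention time not strictly increasing at data row {k}: "
                f"{self.rt[k - 1]!r} -> {self.rt[k]!r}"
            )
        if self.relative_intensity is not None:
            if self.relative_intensity.size != self.rt.size:
                raise ValidationError("relative_intensity length mismatch")
            r = self.relative_intensity
            if np.any(~np.isfinite(r)) or r.min() < 0 or r.max() > 100 + 1e-9:
                raise ValidationError("relative_intensity must lie in [0, 100]")

    @property
    def n(self) -> int:
        """Number of data points."""
        return int(self.rt.size)

    @property
    def dt(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.rt)))

    @property
    def duration(self) -> float:
        """Last retention time in minutes."""
        return float(self.rt[-1])


@dataclass
class StudySample:
    """A chromatogram tagged with subject and sampling condition."""

    chromatogram: Chromatogram
    subject_id: str
    condition: str
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class StudySet:
    """The full cohort: every (subject, condition) pair appears at most once."""

    samples: list[StudySample]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.samples:
            key = (s.subject_id, s.condition)
            if key in seen:
                raise ValidationError(f"duplicate (subject, condition) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[StudySample]:
        return iter(self.samples)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.subject_id not in out:
                out.append(s.subject_id)
        return out

    def by_condition(self, condition: str) -> list[StudySample]:
        """All samples of one condition, in manifest order."""
        return [s for s in self.samples if s.condition == condition]

    def passing(self, condition: str | None = None) -> list[StudySample]:
        """QC-passing samples, optionally restricted to one condition."""
        return [
            s
            for s in self.samples
            if s.qc_pass and (condition is None or s.condition == condition)
        ]

    def with_flags(self, flags: list[tuple[bool, str]]) -> "StudySet":
        """Return a new StudySet with qc flags replaced (same order)."""
        if len(flags) != len(self.samples):
            raise ValidationError("one flag per sample required")
        return StudySet(
            [
                replace(s, qc_pass=ok, qc_reason=reason)
                for s, (ok, reason) in zip(self.samples, flags)
            ]
        )
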