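"""Seeded synthetic breath chromatograms and study cohorts.

The generator emulates the statistical structure the analysis assumes: a
total-ion signal composed of a linearly drifting baseline, a library of
near-Gaussian elution peaks (optionally exponentially modified for tailing)
and additive white Gaussian detector noise,

    y(t) = baseline_level + baseline_drift * t
           + sum_k h_k * g_k(t) + elevation(t) + eps(t),

with subject-level random effects (per-peak apex jitter and log-normal
height multipliers, shared across a subject's three samples — the design is
repeated measures) and condition-level exposure effects: multiplicative
height factors on peaks eluting inside each of the three retention windows
plus additive baseline elevations there. Condition A (pre-exposure) is the
reference with unit factors; B (immediately post) carries the strongest
elevation and C (2 h post) an intermediate one.

Every output is a pure function of ``(profile, seed)``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .groups import Window, default_windows
from .types import Chromatogram, CONDITIONS, StudySample, StudySet, ValidationError

#: Frozen entropy for the default preset's peak library (not a tunable).
_LIBRARY_ENTROPY = 714025

DEFAULT_DURATION_MIN = 45.0
DEFAULT_DT_MIN = 0.005
DEFAULT_N_PEAKS = 125
DEFAULT_N_SUBJECTS = 16


@dataclass(frozen=True)
class ConditionEffect:
    """Per-window exposure effect: multiplicative on peak heights inside the
    window, additive on the baseline there."""

    height_factor: dict[str, float]
    baseline_add: dict[str, float]


def _unit_effect(window_names: tuple[str, ...]) -> ConditionEffect:
    return ConditionEffect(
        height_factor={w: 1.0 for w in window_names},
        baseline_add={w: 0.0 for w in window_names},
    )


def default_effects() -> dict[str, ConditionEffect]:
    """Exposure effects: A reference, B strongest, C intermediate."""
    return {
        "A": _unit_effect(("W_early", "W_mid", "W_late")),
        "B": ConditionEffect(
            height_factor={"W_early": 1.25, "W_mid": 1.6, "W_late": 1.5},
            baseline_add={"W_early": 200.0, "W_mid": 500.0, "W_late": 400.0},
        ),
        "C": ConditionEffect(
            height_factor={"W_early": 1.12, "W_mid": 1.3, "W_late": 1.25},
            baseline_add={"W_early": 100.0, "W_mid": 250.0, "W_late": 200.0},
        ),
    }


def null_effects() -> dict[str, ConditionEffect]:
    """No exposure effect in any condition (for null-calibration runs)."""
    names = ("W_early", "W_mid", "W_late")
    return {c: _unit_effect(names) for c in CONDITIONS}


@dataclass
class SimulationProfile:
    """All generator parameters.

    Units: times in minutes, heights/intensities in instrument units,
    ``baseline_drift`` in intensity per minute, ``height_cv`` a log-normal
    coefficient of variation (dimensionless).
    """

    duration_min: float
    dt_min: float
    peak_rt: np.ndarray
    peak_height: np.ndarray
    peak_sigma: np.ndarray
    peak_tau: np.ndarray | None = None
    baseline_level: float = 2000.0
    baseline_drift: float = 30.0
    noise_sd: float = 300.0
    rt_jitter_sd: float = 0.02
    height_cv: float = 0.3
    effects: dict[str, ConditionEffect] = field(default_factory=default_effects)
    windows: dict[str, Window] = field(default_factory=default_windows)
    n_subjects: int = DEFAULT_N_SUBJECTS
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_rt = np.asarray(self.peak_rt, dtype=float)
        self.peak_height = np.asarray(self.peak_height, dtype=float)
        self.peak_sigma = np.asarray(self.peak_sigma, dtype=float)
        if self.peak_tau is not None:
            self.peak_tau = np.asarray(self.peak_tau, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.duration_min <= 0 or self.dt_min <= 0:
            raise ValidationError("duration_min and dt_min must be positive")
        if self.noise_sd < 0 or self.rt_jitter_sd < 0 or self.height_cv < 0:
            raise ValidationError("noise_sd, rt_jitter_sd, height_cv must be >= 0")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        n = self.peak_rt.size
        if self.peak_height.size != n or self.peak_sigma.size != n:
            raise ValidationError("peak_rt, peak_height, peak_sigma must have equal length")
        if n and (self.peak_rt.min() < 0 or self.peak_rt.max() > self.duration_min):
            raise ValidationError("peak_rt must lie within [0, duration_min]")
        if n and self.peak_height.min() <= 0:
            raise ValidationError("peak heights must be positive")
        if n and self.peak_sigma.min() <= 0:
            raise ValidationError("peak sigmas must be positive")
        ref = self.effects.get("A")
        if ref is None or any(v != 1.0 for v in ref.height_factor.values()) or any(
            v != 0.0 for v in ref.baseline_add.values()
        ):
            raise ValidationError(
                "condition A is the reference: factors must be 1 and elevations 0"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.peak_rt.size)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "duration_min": self.duration_min,
            "dt_min": self.dt_min,
            "peak_rt": self.peak_rt.tolist(),
            "peak_height": self.peak_height.tolist(),
            "peak_sigma": self.peak_sigma.tolist(),
            "peak_tau": None if self.peak_tau is None else self.peak_tau.tolist(),
            "baseline_level": self.baseline_level,
            "baseline_drift": self.baseline_drift,
            "noise_sd": self.noise_sd,
            "rt_jitter_sd": self.rt_jitter_sd,
            "height_cv": self.height_cv,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "windows": {
                k: {"lo": w.lo, "hi": None if np.isinf(w.hi) else w.hi, "closed": w.closed}
                for k, w in self.windows.items()
            },
            "effects": {
                c: {"height_factor": dict(e.height_factor), "baseline_add": dict(e.baseline_add)}
                for c, e in self.effects.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationProfile":
        windows = {
            k: Window(v["lo"], float("inf") if v["hi"] is None else v["hi"], v["closed"])
            for k, v in d["windows"].items()
        }
        effects = {
            c: ConditionEffect(
                height_factor=dict(v["height_factor"]), baseline_add=dict(v["baseline_add"])
            )
            for c, v in d["effects"].items()
        }
        tau = d.get("peak_tau")
        return cls(
            duration_min=d["duration_min"],
            dt_min=d["dt_min"],
            peak_rt=np.asarray(d["peak_rt"], dtype=float),
            peak_height=np.asarray(d["peak_height"], dtype=float),
            peak_sigma=np.asarray(d["peak_sigma"], dtype=float),
            peak_tau=None if tau is None else np.asarray(tau, dtype=float),
            baseline_level=d["baseline_level"],
            baseline_drift=d["baseline_drift"],
            noise_sd=d["noise_sd"],
            rt_jitter_sd=d["rt_jitter_sd"],
            height_cv=d["height_cv"],
            effects=effects,
            windows=windows,
            n_subjects=d["n_subjects"],
            seed=d.get("seed", 0),
        )

    def to_yaml(self, dest: str | Path) -> None:
        Path(dest).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimulationProfile":
        return cls.from_dict(yaml.safe_load(Path(source).read_text()))


@dataclass
class GroundTruth:
    """What the generator actually injected.

    ``peaks``: one row per injected peak per sample (true apex rt, true
    height above the local baseline, sigma, FWHM). ``samples``: one row per
    sample with subject/condition and the per-window factors and elevations
    actually applied.
    """

    peaks: pd.DataFrame
    samples: pd.DataFrame


def _render_peaks(
    t: np.ndarray,
    rts: np.ndarray,
    heights: np.ndarray,
    sigmas: np.ndarray,
    taus: np.ndarray | None,
) -> np.ndarray:
    """Sum of unit-height (exp-modified) Gaussian peaks scaled by heights."""
    y = np.zeros_like(t)
    n = t.size
    for k in range(rts.size):
        rt0, h, s = rts[k], heights[k], sigmas[k]
        tau = 0.0 if taus is None else float(taus[k])
        lo = int(np.searchsorted(t, rt0 - 8.0 * s))
        hi = int(np.searchsorted(t, rt0 + 8.0 * s + 7.0 * tau))
        if hi <= lo:
            continue
        tt = t[lo:hi]
        if tau > 0.0:
            from scipy.stats import exponnorm

            shape = exponnorm.pdf(tt, K=tau / s, loc=rt0, scale=s)
            peak_max = shape.max()
            if peak_max > 0:
                shape = shape / peak_max
        else:
            shape = np.exp(-0.5 * ((tt - rt0) / s) ** 2)
        y[lo:hi] += h * shape
    return y


def _time_grid(profile: SimulationProfile) -> np.ndarray:
    n = int(np.floor(profile.duration_min / profile.dt_min + 1e-9)) + 1
    return profile.dt_min * np.arange(n)


def _elevation(profile: SimulationProfile, t: np.ndarray, condition: str) -> np.ndarray:
    eff = profile.effects[condition]
    elev = np.zeros_like(t)
    for wname, add in eff.baseline_add.items():
        if add:
            elev[profile.windows[wname].mask(t)] += add
    return elev


def _height_factors(profile: SimulationProfile, rts: np.ndarray, condition: str) -> np.ndarray:
    eff = profile.effects[condition]
    fac = np.ones(rts.size)
    for wname, f in eff.height_factor.items():
        if f != 1.0:
            fac[profile.windows[wname].mask(rts)] *= f
    return fac


def simulate_chromatogram(
    profile: SimulationProfile,
    seed: int | None = None,
    sample_id: str = "sim",
) -> tuple[Chromatogram, GroundTruth]:
    """One reference-condition chromatogram (no subject or exposure effects).

    Identical ``(profile, seed)`` gives bit-identical output; ``seed=None``
    falls back to ``profile.seed``.
    """
    if seed is None:
        seed = profile.seed
    t = _time_grid(profile)
    y = profile.baseline_level + profile.baseline_drift * t
    y = y + _render_peaks(t, profile.peak_rt, profile.peak_height, profile.peak_sigma, profile.peak_tau)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, profile.noise_sd, t.size)
    chrom = Chromatogram(
        sample_id=sample_id,
        rt=t,
        intensity=y,
        meta={"sample_id": sample_id, "generator_seed": str(seed)},
    )
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * profile.peak_sigma
    peaks = pd.DataFrame(
        {
            "sample_id": sample_id,
            "peak_id": np.arange(profile.n_peaks),
            "rt_true": profile.peak_rt,
            "height_true": profile.peak_height,
            "sigma": profile.peak_sigma,
            "fwhm_min": fwhm,
            "fwhm_samples": fwhm / profile.dt_min,
        }
    )
    samples = pd.DataFrame(
        [{"sample_id": sample_id, "subject_id": "", "condition": "A"}]
    )
    return chrom, GroundTruth(peaks=peaks, samples=samples)


def simulate_study(
    profile: SimulationProfile, seed: int | None = None
) -> tuple[StudySet, GroundTruth]:
    """A full cohort: ``n_subjects`` subjects times conditions A, B, C.

    Per subject, apex jitter (``rt_jitter_sd``) and log-normal height
    multipliers (``height_cv``, unit mean) are drawn once and shared across
    the subject's three samples; B and C then apply the profile's
    window-specific height factors and baseline elevations. Noise is fresh
    per sample. Deterministic under a fixed seed via spawned bit-generator
    streams (one per subject, one per sample).
    """
    if seed is None:
        seed = profile.seed
    t = _time_grid(profile)
    base = profile.baseline_level + profile.baseline_drift * t

    sigma_ln = float(np.sqrt(np.log1p(profile.height_cv**2)))
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(profile.n_subjects)

    samples: list[StudySample] = []
    peak_rows: list[pd.DataFrame] = []
    sample_rows: list[dict] = []
    for si, sseq in enumerate(subject_seqs):
        subj = f"s{si + 1:02d}"
        children = sseq.spawn(1 + len(CONDITIONS))
        subj_rng = np.random.default_rng(children[0])
        jitter = subj_rng.normal(0.0, profile.rt_jitter_sd, profile.n_peaks)
        mult = subj_rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, profile.n_peaks)
        rts = np.clip(profile.peak_rt + jitter, 0.0, profile.duration_min)

        for ci, cond in enumerate(CONDITIONS):
            fac = _height_factors(profile, rts, cond)
            heights = profile.peak_height * mult * fac
            sid = f"{subj}-{cond}"
            y = base + _render_peaks(t, rts, heights, profile.peak_sigma, profile.peak_tau)
            y = y + _elevation(profile, t, cond)
            if profile.noise_sd > 0:
                noise_rng = np.random.default_rng(children[1 + ci])
                y = y + noise_rng.normal(0.0, profile.noise_sd, t.size)
            chrom = Chromatogram(
                sample_id=sid,
                rt=t,
                intensity=y,
                meta={"sample_id": sid, "subject_id": subj, "condition": cond},
            )
            samples.append(StudySample(chromatogram=chrom, subject_id=subj, condition=cond))
            fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * profile.peak_sigma
            peak_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "subject_id": subj,
                        "condition": cond,
                        "peak_id": np.arange(profile.n_peaks),
                        "rt_true": rts,
                        "height_true": heights,
                        "sigma": profile.peak_sigma,
                        "fwhm_min": fwhm,
                        "fwhm_samples": fwhm / profile.dt_min,
                    }
                )
            )
            eff = profile.effects[cond]
            row: dict = {"sample_id": sid, "subject_id": subj, "condition": cond}
            for wname in profile.windows:
                row[f"factor_{wname}"] = eff.height_factor.get(wname, 1.0)
                row[f"elevation_{wname}"] = eff.baseline_add.get(wname, 0.0)
            sample_rows.append(row)

    truth = GroundTruth(
        peaks=pd.concat(peak_rows, ignore_index=True) if peak_rows else pd.DataFrame(),
        samples=pd.DataFrame(sample_rows),
    )
    return StudySet(samples), truth


def default_breath_profile() -> SimulationProfile:
    """The documented breath-study preset.

    A 45-min run sampled every 0.005 min (0.3 s; 9001 points) with a frozen
    library of 125 Gaussian peaks: apexes at least 0.25 min apart within
    [1.5, 43.5] min, heights log-uniform on [6000, 60000] intensity units,
    sigmas uniform on [0.02, 0.055] min (FWHM 9.4–25.9 samples). Baseline
    2000 + 30/min drift, noise sd 300. Cohort of 16 subjects. The library is
    drawn once from fixed entropy, so every call returns the same preset;
    detection at (prominence 3000, width 8) lands in the 100–150 peak range.
    """
    rng = np.random.default_rng(_LIBRARY_ENTROPY)
    n = DEFAULT_N_PEAKS
    lo, hi, gap = 1.5, 43.5, 0.25
    free = (hi - lo) - (n - 1) * gap
    u = np.sort(rng.uniform(0.0, free, n))
    peak_rt = lo + u + gap * np.arange(n)
    peak_height = 10.0 ** rng.uniform(np.log10(6000.0), np.log10(60000.0), n)
    peak_sigma = rng.uniform(0.02, 0.055, n)
    return SimulationProfile(
        duration_min=DEFAULT_DURATION_MIN,
        dt_min=DEFAULT_DT_MIN,
        peak_rt=peak_rt,
        peak_height=peak_height,
        peak_sigma=peak_sigma,
        peak_tau=None,
        n_subjects=DEFAULT_N_SUBJECTS,
    )


def null_profile() -> SimulationProfile:
    """Default preset with all exposure effects switched off."""
    return dataclasses.replace(default_breath_profile(), effects=null_effects())
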