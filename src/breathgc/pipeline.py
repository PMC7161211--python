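"""End-to-end orchestration: simulate/ingest -> QC -> detect -> compare.

One :func:`run_pipeline` call produces the full artifact set in the output
directory: per-sample chromatogram text files and ground truth (when
simulating), a manifest, per-sample peak-table CSVs, a QC report, the
group summary and difference curves, plus the resolved configuration and a
run log. Identical configuration and seed give byte-identical CSV outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .groups import GroupSummary, compare_groups, write_group_summary
from .io import read_manifest, write_gcms_text, write_manifest, write_peak_table
from .peaks import (
    DEFAULT_PROMINENCE_MIN,
    DEFAULT_REL_HEIGHT,
    DEFAULT_WIDTH_MIN,
    detect_peaks,
)
from .prep import DEFAULT_FILTER_WINDOW, DEFAULT_SNR_THRESHOLD, estimate_snr, qc_filter
from .simulate import SimulationProfile, default_breath_profile, simulate_study
from .types import StudySet

logger = logging.getLogger("breathgc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; resolvable to/from YAML."""

    out_dir: str = "breathgc_out"
    seed: int = 0
    simulate: bool = True
    manifest: str | None = None
    profile: str | None = None  # path to a profile YAML; None = default preset
    prominence_min: float = DEFAULT_PROMINENCE_MIN
    width_min: float = DEFAULT_WIDTH_MIN
    rel_height: float = DEFAULT_REL_HEIGHT
    filter_window: int = DEFAULT_FILTER_WINDOW
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    rt_seconds: bool = False
    make_plots: bool = False
    log_level: str = "INFO"

    def to_yaml(self, dest: str | Path) -> None:
        Path(dest).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(source).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _resolve_profile(config: PipelineConfig) -> SimulationProfile:
    if config.profile is None:
        return default_breath_profile()
    return SimulationProfile.from_yaml(config.profile)


def _write_qc_report(study: StudySet, dest: Path) -> None:
    rows = [
        {
            "sample_id": s.chromatogram.sample_id,
            "subject_id": s.subject_id,
            "condition": s.condition,
            "snr": estimate_snr(s.chromatogram),
            "qc_pass": s.qc_pass,
            "reason": s.qc_reason,
        }
        for s in study
    ]
    pd.DataFrame(rows).to_csv(dest, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> GroupSummary:
    """Run all stages; writes artifacts under ``config.out_dir``.

    On a stage failure a ``FAILED`` marker file naming the stage is left in
    the output directory and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    logger.info("breathgc %s", __version__)
    logger.info("resolved config: %s", dataclasses.asdict(config))
    config.to_yaml(out / "resolved_config.yaml")

    stage = "ingest"
    try:
        if config.simulate:
            stage = "simulate"
            profile = _resolve_profile(config)
            study, truth = simulate_study(profile, config.seed)
            chrom_dir = out / "chromatograms"
            chrom_dir.mkdir(exist_ok=True)
            rel_paths = []
            for s in study:
                p = chrom_dir / f"{s.chromatogram.sample_id}.txt"
                write_gcms_text(s.chromatogram, p)
                rel_paths.append(str(p.relative_to(out)))
            write_manifest(study, out / "manifest.csv", rel_paths)
            truth.peaks.to_csv(out / "ground_truth_peaks.csv", index=False, float_format="%.12g")
            truth.samples.to_csv(out / "ground_truth_samples.csv", index=False, float_format="%.12g")
            logger.info("simulated %d samples (%d subjects)", len(study), profile.n_subjects)
        else:
            if not config.manifest:
                raise FileNotFoundError("no manifest given and simulation not requested")
            study = read_manifest(config.manifest, rt_seconds=config.rt_seconds)
            logger.info("ingested %d samples from %s", len(study), config.manifest)

        stage = "qc"
        study = qc_filter(study, config.snr_threshold)
        _write_qc_report(study, out / "qc_report.csv")
        n_pass = len(study.passing())
        logger.info("QC: %d/%d samples pass (threshold %g)", n_pass, len(study), config.snr_threshold)

        stage = "detect"
        peaks_dir = out / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for s in study.passing():
            table = detect_peaks(
                s.chromatogram,
                prominence_min=config.prominence_min,
                width_min=config.width_min,
                rel_height=config.rel_height,
            )
            write_peak_table(table, peaks_dir / f"{s.chromatogram.sample_id}.csv")
        logger.info("detected peaks for %d samples", n_pass)

        stage = "compare"
        summary = compare_groups(study, filter_window=config.filter_window)
        write_group_summary(summary, out)
        logger.info(
            "group means: n=%s over %d grid points",
            summary.n_samples,
            summary.grid.size,
        )
        if config.make_plots:
            from .plotting import plot_group_means

            plot_group_means(summary, out / "group_means.png")
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return summary
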