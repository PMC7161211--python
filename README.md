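# breathgc

Analysis of exhaled-breath GC–MS total-ion chromatograms for exposure
studies. The motivating setting is breathomics of swimmers in chlorinated
indoor pools: each subject's breath is sampled before exposure (condition
A), immediately after (B) and 2 h after (C), and the question is whether and
where along the retention-time axis the volatile-organic-compound profile
changes. `breathgc` provides the full desk-side pipeline — chromatogram
import and validation, peak detection with per-peak features, moving-average
filtering, signal-to-noise quality control, and condition-wise mean-signal
comparison — together with a seeded synthetic chromatogram/cohort generator
that stands in for raw instrument data and supplies ground truth for every
injected peak.

## The method

A chromatogram is a sampled signal *y(t)* (absolute detector intensity
versus retention time *t* in minutes). Peaks are interior local maxima
selected by two criteria computed from scratch:

- **Topographic prominence** — the apex height above the highest saddle
  separating the peak from higher ground. Scanning outward from apex *i*
  until a strictly higher sample (or the signal edge), the lowest sample on
  each side is that side's *base*; prominence is
  `y[i] − max(left_min, right_min)`.
- **Width at relative height** — the horizontal extent at
  `y[i] − rel_height · prominence` (default `rel_height = 0.5`), linearly
  interpolated between samples, reported in samples and minutes.

A peak is kept when prominence ≥ 3000 intensity units **and** width ≥ 8
samples — the operating point at which a breath chromatogram yields on the
order of 100–150 peaks. For each peak the five features *retention time,
absolute intensity, prominence, width, area* are recorded (area is the
trapezoidal integral above the chord joining the prominence bases, so it is
shift-invariant) and persisted as CSV.

For group comparison, every QC-passing signal (robust SNR =
`(p95 − median) / noise_sd` with `noise_sd` from the MAD of first
differences; threshold 5) is interpolated onto a common grid, low-pass
filtered with a centred moving average (window 301 samples ≈ 1.5 min), and
averaged per condition. Differences B−A, C−A, B−C are summarised in three
retention windows: readily volatile compounds in [0, 4) min, semi-volatile
in [16, 19] min, hardly volatile beyond 30 min.

The transform-shaped operations are scikit-learn estimators
(`PeakDetector`, `MovingAverageSmoother`, `SNRQualityFilter`,
`GroupMeanComparator`) with plain-function wrappers (`detect_peaks`,
`moving_average`, `qc_filter`, `compare_groups`).

## Worked example

```python
import breathgc as bg

profile = bg.default_breath_profile()            # 45-min run, 125-peak library, n=16
chrom, truth = bg.simulate_chromatogram(profile, seed=0)
table = bg.detect_peaks(chrom)                   # prominence >= 3000, width >= 8
print(f"{table.n_peaks} peaks detected; SNR = {bg.estimate_snr(chrom):.1f}")

study, _ = bg.simulate_study(profile, seed=0)    # 16 subjects x conditions A/B/C
study = bg.qc_filter(study, snr_threshold=5.0)
summary = bg.compare_groups(study)
print(summary.window_stats.round(1).to_string(index=False))
```

prints

```
125 peaks detected; SNR = 54.4
condition  window    mean  baseline  n
        A W_early  5603.8    2018.0 16
        A   W_mid  8463.1    5451.1 16
        A  W_late  8789.9    5681.8 16
        B W_early  6530.9    2221.4 16
        B   W_mid 12119.3    6835.8 16
        B  W_late 12010.3    7227.2 16
        C W_early  6047.9    2113.9 16
        C   W_mid 10289.1    6141.7 16
        C  W_late 10399.8    6440.7 16
```

The peak count sits in the calibrated 100–150 range; the window table shows
the post-exposure elevation — condition B highest, C intermediate, A lowest
— in the semi-volatile (W_mid) and hardly volatile (W_late) windows, the
expected signature of exposure to chlorination by-products. `mean` is the
mean filtered intensity in the window, `baseline` its 10th percentile (a
peak-robust baseline estimate), `n` the samples entering each group mean.

The same pipeline runs from the shell:

```sh
breathgc run -o out/ --seed 0            # simulate -> QC -> detect -> compare
breathgc detect out/chromatograms/s01-A.txt -o s01A_peaks.csv \
    --prominence 3000 --width 8
breathgc qc out/manifest.csv -o qc.csv --snr-threshold 5
```

producing per-sample peak tables, a QC report, the group summary and
difference-curve CSVs, a resolved config and a run log; identical config
and seed reproduce the CSVs byte for byte.

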