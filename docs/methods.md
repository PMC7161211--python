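# Methods

## Signal model

A breath total-ion chromatogram is modelled as

    y(t) = b0 + b1·t + Σ_k h_k·g_k(t) + e(t),   t ∈ [0, T] minutes,

with constant baseline `b0`, linear drift `b1` (instrument units per
minute), a library of elution peaks, and i.i.d. Gaussian detector noise
`e(t)` with standard deviation `noise_sd`. Each `g_k` is a unit-height
Gaussian centred at apex `rt_k` with width `sigma_k`; setting a per-peak
`tau_k` replaces it with a unit-height exponentially modified Gaussian,
the standard shape for tailing GC peaks. Peaks are rendered within ±8σ
(plus 7τ for tailed peaks) of the apex; the truncated mass is below 1e-9
of the peak, far inside the 0.1% tolerance at which mass conservation is
asserted.

## Peak detection

Local maxima are interior samples strictly above both neighbours; a flat
plateau strictly above both neighbours counts once, at its middle sample
(lower middle for even plateaus) — a fixed convention so detection is
deterministic. Topographic prominence scans outward from the apex to the
nearest strictly higher sample (or the signal edge) on each side; the
lowest sample in each stretch is the base (ties resolved to the sample
nearest the apex), and prominence is apex minus the higher base value.
The prominence search window is unbounded — the whole signal. Width is
measured at `apex − rel_height·prominence` with linear interpolation
between samples; `rel_height` defaults to 0.5, the common
width-at-half-prominence convention. Width thresholds are interpreted on
the sample grid (a "width ≥ 8" cut means 8 grid steps, 0.04 min at the
default sampling); the width is additionally reported in minutes. Peak
area is the trapezoidal integral between the prominence bases minus the
chord joining them, clipped at zero: chord subtraction makes area
invariant to adding a constant, and the clip guards degenerate
plateau-shaped "peaks".

These primitives are certified two ways in the test suite: exactly
against an exhaustive O(n²) contour-search oracle on random
integer-valued signals, and exactly against `scipy.signal`'s
prominence/width routines on the same inputs. The package's own scan
implementation — not the scipy one — is what the pipeline runs.

## Filtering and QC

The low-pass filter is a centred moving average with a *shrink* edge
rule: the window truncates symmetrically at the edges, so output length
equals input length, constants are fixed points, and the operator is
linear (it therefore commutes exactly with averaging across samples).
The default window, 301 samples ≈ 1.5 min, smooths away individual peaks
while preserving the window-scale trends the group comparison targets;
it is configurable.

The QC statistic is SNR = (p95(y) − median(y)) / noise_sd with
noise_sd = 1.4826·median(|Δy|)/√2 — the median absolute first difference
rescaled to a Gaussian sigma (√2 undoes the variance doubling of
differencing). The estimator needs no peak detection, is exactly shift-
and scale-invariant, and returns +∞ (always passes) for noiseless
signals. The pass threshold defaults to 5, a conventional detection
floor; failing samples are flagged with a reason string, never deleted.

## Group comparison

Samples are linearly interpolated onto a common grid running from the
latest per-sample start to the earliest end (no extrapolation), stepped
at the median sampling interval. Filtering is applied per sample before
averaging; by linearity the result equals filtering the mean, which the
tests assert to machine precision. Window statistics (mean intensity and
a 10th-percentile baseline estimate — a low quantile is robust to peaks
riding on the baseline) are computed from the filtered mean signals, and
the three pairwise difference curves B−A, C−A, B−C are reported on the
filtered means. Window closures follow their verbal definitions:
[0, 4) min, [16, 19] min, (30, end] min.

## Synthetic cohort: what it emulates and what it does not

The default preset is one fixed, documented operating point, drawn once
from frozen entropy so every construction is identical:

| parameter | default | rationale |
| --- | --- | --- |
| run length T | 45 min | late-window compounds elute past 30 min, with margin |
| sampling dt | 0.005 min (0.3 s) | makes an 8-sample width ≈ 2.4 s, a plausible GC peak width |
| library size | 125 peaks | centre of the expected 100–150 detection range |
| apex spacing | ≥ 0.25 min in [1.5, 43.5] | keeps neighbouring peaks resolved at the widest sigma |
| heights | log-uniform [6 000, 60 000] | decade of dynamic range, all above the 3 000 prominence floor |
| sigma | uniform [0.02, 0.055] min | FWHM 9.4–25.9 samples, all above the width-8 floor |
| baseline | 2 000 + 30/min drift | visible drift without dominating the signal |
| noise sd | 300 | one tenth of the prominence floor, the level at which ≥95% sensitivity is asserted |
| rt jitter sd | 0.02 min | subject-level retention alignment error, small vs. spacing |
| height CV | 0.3 | log-normal between-subject abundance variation, unit mean |
| cohort | 16 subjects × A/B/C | repeated-measures design of the study being emulated |

Exposure effects are multiplicative on the heights of peaks eluting
inside each retention window and additive on the baseline there —
matching the two observed phenomena, elevated signal intensity and
elevated baseline. Condition A is the neutral reference (validated:
factors 1, elevations 0); B carries the strongest effect
(×1.25/×1.6/×1.5 and +200/+500/+400 across early/mid/late) and C, two
hours after exposure, an intermediate one (×1.12/×1.3/×1.25,
+100/+250/+200). The C-between-A-and-B ordering is an assumption of the
generator, configurable per profile. Per-subject random effects (jitter,
height multipliers) are shared across a subject's three samples, as a
repeated-measures design requires; all randomness derives from one seed
through spawned `SeedSequence` streams, one per subject and one per
sample, so cohorts are bit-reproducible.

What the generator does **not** emulate: the mass-spectral (m/z)
dimension, physicochemical retention or chlorination chemistry,
heteroscedastic detector noise, retention-time warping beyond rigid
per-subject jitter, and co-eluting unresolved peak clusters. Passing
tests therefore certify the numerics and the recovery behaviour of the
pipeline under its stated model, not instrument-specific artifacts of
real breath data.

## Numerical and procedural choices

- Input dialect: whitespace runs or single commas delimit columns;
  decimal points only; leading non-numeric lines are headers (`key:
  value` parsed, others kept verbatim). Output is strictly
  comma-separated; floats carry 12 significant digits so write→read is
  the identity at that precision.
- Retention times are minutes everywhere. A file whose retention times
  exceed 120 is rejected as probably second-valued, with an explicit
  `rt_seconds` conversion flag as the escape hatch.
- The relative-intensity column is optional, validated to [0, 100], and
  never used in computation (absolute intensity is authoritative).
- Ground-truth threshold qualification for recovery checks is judged on
  the noise-free composite signal: overlap between neighbouring peaks
  can depress a peak's effective prominence below its injected height,
  so apex height alone would mislabel marginal peaks. The noisy-case
  matching radius is half the peak's true FWHM.
- Problem sizes in the test suite: the default 9001-point chromatogram
  and 48-sample cohort are used directly; Monte-Carlo style checks
  (null-configuration calibration, effect-direction recovery) use 10–20
  seeds, and reduced cohorts (10 peaks, 3 subjects, 32-min runs) stand
  in where only plumbing is exercised.

## Known limitations

- No deconvolution: heavily overlapping peaks are detected as one or
  with depressed prominence; the default library enforces spacing that
  keeps this rare.
- No baseline-correction stage — baseline elevation is treated as
  signal, which is what the group comparison measures; analyses that
  need nuisance-baseline removal must add it upstream.
- No inferential statistics: group differences are reported as curves
  and window summaries, not tests or p-values, and no classifier is
  included.
- The additive window elevations are boxcar-shaped, so simulated
  baselines step at window boundaries; the moving-average trend curves
  smear these steps over ~1.5 min, as they would any sharp trend change.
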