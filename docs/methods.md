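# Methods

This note documents the models behind `tribogait`, the defaults that
matter, what the synthetic data emulate (and what they do not), and the
numerical choices made where the design was genuinely open.

## TENG transduction model

The sensor response is phenomenological, not electrostatic: it reproduces
the three characterized marginal trends of a contact–separation
triboelectric sensor — per-cycle peak voltage increasing with applied
force, drive frequency, and electrode area — with the simplest separable
form

    V(p, f, A) = min(v_max, g(f) · (A / A_ref) · S(p)),  p = 10 F / A [kPa].

* `S(p)` is the continuous two-regime linear sensitivity through the
  origin with slopes `slope_low = 0.308 V/kPa` (below the breakpoint) and
  `slope_high = 0.198 V/kPa` (above). The slope reduction represents
  partial saturation as the contact interface approaches full engagement.
  The slopes are treated as area-normalized sensitivities applied at the
  reference area.
* `breakpoint_kpa = 5.0` places the regime change inside the 0.5–10 kPa
  band that both the bench protocol (5–20 N over 6.6–19.6 cm²) and walking
  loads occupy, so both regimes are exercised under realistic input.
* `A_ref` is calibrated in closed form so the largest sensor (19.6 cm²)
  returns exactly `v_max = 9.94 V` at the 20 N / 3 Hz bench reference:
  `A_ref = A · S(10·F/A) / v_max ≈ 5.07 cm²`. Note that the reference
  condition cannot be met by choosing the breakpoint alone: at 20 N over
  19.6 cm² the pressure is only ~10.2 kPa, and `S` there is at most
  `0.308 × 10.2 ≈ 3.1 V`, far below 9.94 V, so the amplitude scale has to
  come from the area factor. Calibrating `A_ref` is the only free knob
  consistent with area-normalized slopes.
* `g(f) = clip((f/3)^γ, 0.5, 1.6)` with `γ = 0.35` is a modelling default:
  only the monotone increase of amplitude with frequency is characterized,
  not its shape. It is normalized to 1 at the 3 Hz bench reference so the
  force-linearity numbers are unaffected by the choice of γ.
* Saturation is a hard clamp at `v_max`. Whether the physical saturation
  is hard or asymptotic is not characterized; the clamp is the simpler
  choice and only matters above the calibrated maximum.

A structural consequence of the separable form worth knowing: below the
breakpoint, `(A/A_ref)·slope_low·(10F/A)` is independent of `A`, so the
area–voltage relation is strictly increasing only where per-sensor
pressures exceed the breakpoint (true at bench force levels) and exactly
flat in the deep low-pressure regime.

### Bench traces and peak extraction

Synthetic bench traces place one biphasic spike pair per contact cycle
(positive contact spike of model amplitude, 0.6× negative release spike,
Gaussian width 5% of the period), with the release spike far enough from
the contact crest that the crest equals the model peak. Peak extraction
finds local maxima on a short moving-average-smoothed copy (threshold
3×MAD with an excursion fallback for noise-free traces, minimum separation
half a period), then reads each amplitude as the vertex of a least-squares
parabola fitted to the raw trace around the detected index. The two-stage
scheme avoids both the upward selection bias of arg-maxing noise and the
downward attenuation bias of reading amplitudes off the smoothed trace.

### Segmented sensitivity fit

`fit_sensitivity` fits `v = c0 + c1·p + c2·(p−b)+` by linear least squares
at fixed breakpoint `b` (continuity is built into the basis), scans ~200
candidate breakpoints across the interior of the pressure range (keeping
at least two points per side), and refines the best candidate by bounded
scalar minimization (xatol 1e-12). On noise-free model sweeps this
recovers the generating slopes to well below 1e-6 V/kPa. Perfectly
collinear data are detected by the single-line residual, flagged, and
returned as equal slopes with the breakpoint at the pressure midpoint.

## Synthetic gait trials

Each 2-minute walk trial is generated as follows; defaults are the study
conditions of a mixed rehabilitation cohort.

* **Stance template.** Total per-foot load is a double-bump curve (weight
  acceptance and push-off), two Gaussians at 25% and 75% of stance
  (SD 10% of stance), stance = 60% of the gait cycle. The template is
  edge-corrected so load rises from and returns to exactly zero at foot
  contact and toe-off — without this, the residual 4% bump value at the
  stance boundary makes the sampled waveform discontinuous there and
  stride-to-stride reproducibility becomes a floating-point knife edge.
* **Region timing.** Regional shares follow Gaussian activations over
  stance phase (heel 0.22, medial arch 0.50, forefoot 0.72, big toe 0.85)
  scaled by baseline weights (heel 0.40, forefoot 0.24, big toe 0.26,
  arch 0.10) and renormalized, so shares sum to 1 at every stance sample.
  The baselines put the typical arch index near 15% and the heel (lateral
  set) share near 40%, matching the low arch indices and ~44–46% lateral
  dominance expected for mixed cohorts.
* **Step count.** Exactly `round(duration · cadence / 60)` ground-truth
  steps are generated, split between the feet with a half-stride offset
  (left leads when odd). Cohort cadences span 80–130 steps/min, i.e. total
  footstep rates of 1.3–2.2 Hz, inside the 1–3 Hz band where the sensors
  are characterized.
* **Asymmetry.** A signed percentage `a` scales the per-side *recorded
  signal* amplitude by (1 ∓ a/100) (positive = right-dominant). The scale
  is applied to the transduced voltage rather than the driving force
  because the asymmetry index is amplitude-based in the signal domain; a
  force-domain scale would be compressed by the concave transduction and
  the injected value would no longer be the recovery target.
* **Flatfoot loading.** Affected feet move 12 percentage points of load
  share to the medial arch (taken proportionally from the other regions)
  plus a 5-point big-toe→forefoot transfer in the lateral direction.
  Under the default angular layout the arch sits medially (195°), so the
  arch-dominant shift moves the per-foot CoP proxy medially on net; the
  classifier therefore operates primarily through the arch index, and the
  lateral transfer magnitude is configurable.
* **Transduction and digitization.** Regional forces (peak 30 N per foot,
  a default keeping pressures in the characterized sub-saturation band)
  are transduced with the sensor model at the per-foot contact frequency,
  noise (SD 0.05 V) added, and digitized to 12-bit counts over a 10 V
  reference.
* **IMU.** One Gaussian angular-velocity pulse (2 rad/s, SD 50 ms) per
  ipsilateral step at 10 dB peak SNR; a matching accelerometer pulse
  train. One merged channel pair per limb is emitted.
* **Cohort structure.** Sex-specific demographics (females 1.63 ± 0.08 m,
  66.3 ± 18.3 kg, age 34 ± 17.5 y; males 1.79 ± 0.07 m, 75.9 ± 11.9 kg,
  27 ± 8.7 y; ages truncated to 9–68), cadence = β₀ + β₁·age + ε with β₁
  set from the realized age spread to hit a population age–cadence
  correlation of −0.306 around 100.6 ± 10.1 steps/min, asymmetry
  ~ N(−1.4, 18.7)% truncated to ±100, flatfoot probability 0.547 (half
  bilateral), multimorbidity 37.7% with category weights proportional to
  the seven-group prevalence of a 53-patient mixed cohort. History texts
  are assembled from per-category keyword pools; the recorded
  category-truth is what the categorization rule yields for the text
  (some phrases are legitimately multi-tagged — gonarthrosis is both a
  knee condition and an arthrosis).

All randomness descends from a single seed through a splittable seed
sequence; fixture regeneration with the same seed is byte-identical.

**What the generator does not emulate:** real plantar-pressure waveform
idiosyncrasy (only the canonical double bump), sensor drift and
hysteresis, gait variability within a trial (cadence and timing are
constant), IMU axes and orientation effects, turning at corridor ends,
and any kinematic chain above the ankle. Passing recovery tests therefore
demonstrates that the pipeline measures what the model injects under
idealized-but-noisy conditions, not that it is validated on real gait.

## Per-trial metrics: numerical choices

* **CoP proxy.** Bilateral scope uses one circle in the body frame
  (+x = subject's right), with left-foot angles mirrored across the
  anteroposterior axis; per-foot scope uses each foot's local frame
  (+x = lateral). Samples with total load below 1e-6 of full scale are
  flagged undefined, never interpolated.
* **Asymmetry smoothing.** The per-side sums are smoothed with a 1.5 s
  moving average (≈ one stride) before the ratio. The time-average of the
  *raw* instantaneous ratio does not recover an injected amplitude
  asymmetry: during single support the ratio saturates at ±100 and the
  two sides cancel, leaving only ~10% of the injected value carried by
  double-support samples. Smoothing over the stride scale turns the index
  into an amplitude-dominance measure, which is the quantity of interest.
  Setting the window to 0 restores the raw ratio.
* **Step detection.** Peaks on the (4th-order Butterworth, 6 Hz
  low-passed) gyro or heel channel, requiring prominence
  ≥ max(3×MAD, 0.35×robust excursion) and height ≥ median + 0.5×robust
  excursion, with 0.3 s minimum separation. The height term is essential:
  for sparse pulse trains the MAD is computed mostly from the quiet
  baseline and by itself admits noise peaks between steps.
* **Strides.** Valid stride durations are 0.4–2.5 s (standard
  physiological bounds); invalid strides are dropped and counted. Stride
  waveforms are linearly resampled to 100 gait-cycle points.
* **Arch metrics.** arch index = 100 × arch/(forefoot+arch+heel) mean
  loads; lateral share over the configured lateral region set (default
  {heel}, chosen so typical lateral shares sit in the 40–46% band and
  normal feet stay below the 50% flag threshold). Flatfoot-type loading is
  flagged when arch index ≥ 25 or lateral share ≥ 50 (both configurable).
  This is a sensor-load stand-in for radiographic arch measures, not a
  claim of equivalence.
* **Cadence.** 60·(n−1)/(t_last−t_first) over pooled events; requires ≥ 4
  events. IMU- and heel-derived cadence agree within 2 steps/min on
  synthetic trials, so either source may be used.

## Cohort statistics

Categorization is case-insensitive substring matching after punctuation
stripping against seven keyword sets (spine/back, knee, ankle/foot, hip,
fractures/breaks, arthritis/joint, other); unmatched text falls to
`other`, multimorbid texts are multi-tagged, and prevalence counts unique
participants. Correlations use scipy's Pearson/Spearman with pairwise
deletion; binary history tags against continuous metrics use Spearman on
0/1 coding. Category comparisons run both one-way ANOVA and
Kruskal–Wallis and always carry an `exploratory` flag because groups
overlap under multimorbidity; raw p-values are reported, with a
Benjamini–Hochberg helper available but off by default. BMI bins are
left-closed, right-open except the final bin, and partition (0, ∞).

## Problem sizes

Recovery and classification checks use the sizes at which their targets
are defined: single 120 s trials at 100 Hz for cadence/stride/asymmetry
recovery, 30 s trials for flatfoot classification (trial-mean loads
stabilize within seconds, so the shorter trial measures the same
quantity across the 200-participant × 10-seed design), 50-point sweeps
and 100 noise seeds for the sensitivity fit, and n = 1000 cohorts for the
age–cadence calibration band.

## Known limitations

* The transduction model is separable and phenomenological; real TENG
  output couples force, frequency and area through charge dynamics and
  shows hysteresis the model omits.
* The flatfoot flag thresholds are design defaults validated only against
  the generator's own effect sizes.
* The asymmetry index depends on the smoothing window at sub-stride
  scales; windows much shorter than a stride re-introduce single-support
  saturation.
* Cohort-level statistics on synthetic data inherit the generator's
  simplifications; category-comparison p-values are exploratory by
  construction.
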