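# Methods

## Signal model

A recording is a movie `F[t, r, c]` of non-negative counts (16-bit camera
range) with a strictly increasing time base and a stimulus epoch
`[stim_onset, stim_offset)`. The fractional fluorescence change is

    dff[t, r, c] = (F[t, r, c] − F0[r, c]) / F0[r, c],

with `F0` the per-pixel mean over the **baseline window** — by default every
frame strictly before stimulus onset (at least two are required). ΔF/F is
stored unitless and rendered as percent only at reporting boundaries, which
avoids double-scaling errors. Pixels with `F0 = 0` (dead pixels, the dural
vein) are masked and excluded from every downstream statistic; they are never
interpolated, because interpolating across the vein would fabricate signal
where none can be observed.

By construction the baseline-window mean of `dff` is 0 per pixel, and `dff`
is invariant under a global multiplicative gain; both are enforced as tests.

## Phase segmentation

The evoked transient is biphasic: flavoprotein oxidation produces a positive
deflection (light phase), the subsequent reduction a sub-baseline deflection
(dark phase). On a ROI-mean trace the light phase is the maximal contiguous
post-onset run exceeding a noise band of `k` baseline standard deviations
(`k = 2` by default, a conventional detection band; configurable and echoed
into outputs). The dark phase is the first contiguous run after the light
phase below `−band`; it may be absent. A trace that never exceeds the band
yields a *no-response* flag rather than an exception, and the intensity then
falls back to the global post-onset maximum so that a flagged value can still
enter group tables.

Ties for the longest run go to the earliest run. Frame ranges are half-open,
0-based, row-major; the upper image half is the left/ipsilateral cord side by
default (configurable orientation tag).

## ROI metrics

* **AFI intensity** — maximum of the ROI-mean ΔF/F over the light phase, in
  percent. ROI-mean excludes masked pixels and reports the valid-pixel count.
* **Area of excitation** — number of valid pixels whose *maximum* ΔF/F over
  an analysis window (default: the light phase; a frame-wise `mean` mode is
  available) strictly exceeds a predefined level, default **0.25 % ΔF/F**.
  The level is a convention that must simply be held constant across
  recordings; 0.25 % sits mid-range of the ±0.75 % display range typical for
  this preparation, and it is echoed into every output. A pixel exactly at
  the level is *not* counted ("above" is read strictly). Areas are reported
  in pixels and in mm² via `(pixel_size/1000)²`, and split at the horizontal
  midline into ipsi-/contralateral counts (configurable midline row).

The max-over-window statistic matches an intensity defined as a maximum, but
it is positively biased under noise: the per-pixel maximum of ~50 noisy
frames sits well above zero, so single-pixel areas at low SNR are
noise-dominated. Group comparisons of areas remain valid (the bias is common
to all arms), and the `mean` mode provides a low-bias alternative.

## Treatment analysis

Post-treatment responses are expressed as `100 · after/before` (percent of
before-treatment), separately for intensity and area. Baselines below a
configurable floor make the ratio undefined (NaN, warned, excluded from group
means). Before-treatment is coded −30 min; post-treatment timepoints are
0, 5, …, 60 min after cessation of 30 min of SCS or sham.

* **Before-vs-T0**: two-sided one-sample t of the relative values at T = 0
  against 100 % (equivalent to the paired t on raw pairs). All values exactly
  100 → t = 0, p = 1 by convention.
* **Time-course regression**: OLS of the per-timepoint *cohort mean* relative
  intensity against time over T = 0–60 (13 timepoints), reporting slope
  (%ΔF/F·min⁻¹), intercept, Pearson r and the two-sided slope p. The printed
  slopes describe the mean trajectory, hence the cohort-mean default; a
  pooled per-animal-point mode exists for sensitivity analysis. Constant
  response → slope 0, p = 1. Missing timepoints are dropped pairwise, never
  imputed.
* **Naïve-vs-neuropathic ANOVA**: two-way ANOVA (animal type × side, with
  interaction) via OLS + Type II sums of squares (robust default for the
  unbalanced 20-vs-13 design; the SS type is recorded). Empty cells and
  single-observation cells raise named errors.
* **Palpation contrast**: two-sided unpaired t, Welch by default (pooling
  unspecified in the field convention; the mode is recorded).

No multiple-testing correction is applied across the AFI endpoint family;
Bonferroni is applied only to the behavioral pairwise comparisons.

## Behavioral endpoints

Von Frey: withdrawal counts out of five per ascending filament; threshold =
force of the first filament with ≥ 3 withdrawals, else the maximum force with
a censored-high flag. The default filament series 0.4–26 g is the standard
rat set; thresholds are therefore snapped to that discrete grid. Hotplate:
latency censored at 30 s, with exactly-30 s counted as censored (the animal
did not respond within the window).

The day effect (days 0/10/12/14) is a one-way repeated-measures ANOVA
(complete cases; incomplete animals dropped with a note), followed by paired
t-tests of day 0 versus each later day, Bonferroni factor 3. A
Greenhouse–Geisser correction is available and off by default; the flag and
epsilon are recorded. With zero within-subject variation F = 0, p = 1 by
convention.

## Synthetic generator

**Movie**: `frames = round(B·(1 − bleach·t)·(1 + k(t)·G(r,c)) + noise)`.

* Kernel `k(t) = a·[(1 − e^{−t/τ₁})e^{−t/τ₂} − u·(1 − e^{−t/τ₂})e^{−t/τ₃}]`
  with defaults τ₁ = 1 s, τ₂ = 6 s, τ₃ = 10 s, u = 0.6 — illustrative values
  giving a light phase spanning roughly the 10 s stimulus and a visible dark
  phase. Inside the renderer the kernel time course is normalized to unit
  peak over the rendered frames, so the amplitude parameter *is* the rendered
  peak ΔF/F (the package's amplitude convention; it makes noiseless
  ground-truth recovery exact).
* Spatial profile `G`: flat-top disc (plateau radius H/8, Gaussian shoulder
  σ = H/16) per side, so an ROI inside the plateau reads the full amplitude
  and the supra-threshold contour has a closed-form radius
  `R = plateau + σ·sqrt(2·ln(a/threshold))`.
* Default amplitudes: noxious ipsi 0.5 %, contra 0.2 %; palpation 0.3 % ipsi
  in neuropathic animals only (allodynia), 0 in naïve. All within the
  ±0.75 % display range; all echoed into sidecars. Note these illustrative
  side amplitudes imply a side effect a real cohort need not show.
* Noise: Gaussian with SD `noise_scale·sqrt(counts)` (Poisson approximation,
  valid at these count levels; `noise_scale = 0.5` models camera gain).
  Baseline B = 50000 counts. These defaults keep the max-statistic bias of
  AFI intensity below 10 % of the amplitude while leaving per-pixel SNR < 1,
  consistent with the low SNR of the preparation. Headroom above 16 bits is
  rejected before rendering; the clipped fraction is reported.
* Artifacts: optional linear bleaching; a 3-row vein band at the midline
  rendered at a constant 0 so the masking path is exercised. Noiseless
  renders skip integer quantization (an idealized scene exposing exact
  ground truth); quantization is on whenever noise is on.
* Test-scale default is 64×64 (the acquisition-scale field is 512×512); all
  geometry derives from the image size.

**Treatment cohorts**: per animal,
`relative(t) = S0 + β·t + animal_effect + noise` (percent of before), with
presets: SCS S0 = 45 %, β = 0.92 %·min⁻¹, between-animal SD 10, within SD 35;
sham S0 = 100 %, β = 0.19 %·min⁻¹, within SD 60 (noise chosen from the t/OLS
noncentrality formulas so the sham slope is statistically indistinguishable
from zero while the SCS suppression and slope are reliably detected at
n = 7 + 6); an exact-null preset (β = 0) serves calibration runs. Values are
left unclipped so slope recovery stays unbiased.

**Behavioral cohorts**: latent sensitivity on the filament-index scale with a
probit psychometric function generating per-filament withdrawal counts
(Binomial(5, p)); neuropathy lowers the latent index by 2.5–3.5 steps across
post-operative days. Hotplate latencies are Gaussian around 11 s, lowered
3.5–4.5 s by neuropathy, floored at 1 s and censored at 30 s.

What the generator does *not* emulate: motion, hemodynamic/absorption
confounds, optics (PSF, depth), spatially correlated noise, and
animal-to-animal kernel-shape variation. Passing tests therefore certify the
analysis code and its statistical calibration, not robustness to those
real-data artifacts.

## Problem sizes and numerics

Monte-Carlo suites use 100–200 seeded replicates; multi-replicate pipeline
runs use a reduced 32×32 / 12 s / 5 fps scene (false-positive rates are
scale-invariant, so calibration transfers). Null calibration of the
repeated-measures ANOVA uses the hotplate endpoint, whose values are
continuous; the von Frey endpoint lives on the discrete filament grid, where
exact F-test calibration is not guaranteed. All seeds derive from a single
`SeedSequence`, and every generator is deterministic given its seed.

Known limitations: the area statistic's noise bias (above); the paired t and
ANOVA assume approximate normality of small samples; no mixed-effects or
censored-data modeling of the AFI endpoints; automated ROI placement is out
of scope.
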