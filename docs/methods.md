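# Methods

This note records the modeling assumptions, parameter conventions and
numerical choices behind `psft`, and what the synthetic-data tests do and
do not establish about real scanner data.

## Experimental timeline

A run is an initial 10 s blank followed by six 40.5 s task blocks, each
with a trailing 10 s blank — 313 s sampled at TR = 1 s. Three attention
conditions (attend the 0.5 cpd letter stream, the 2 cpd stream, or
fixation) are interleaved pseudorandomly, two blocks each per run; a
nine-run session gives 18 blocks per condition. The probe hemifield shows
40 SF-bandlimited noise stimuli per block at a 10 Hz refresh, with center
SFs log-spaced from 0.1 to 12 cpd.

Two timing conventions are not dictated by the block arithmetic and are
fixed here as follows:

- **Within-block SF schedule.** 40.5 s at 10 Hz is 405 frames; each of the
  40 levels appears exactly once per block as a seeded permutation with a
  1.0 s dwell (10 frames), the final level holding the 5 leftover frames.
  One-presentation-per-level is the simplest schedule consistent with 40
  stimuli in a 40.5 s block; resampling with repetition would change
  nothing downstream except the per-block SF histogram.
- **TR assignment at half-TR boundaries.** Because a block-plus-blank unit
  lasts 50.5 s, block onsets alternate between whole- and half-TR times. A
  TR belongs to a block segment iff its midpoint falls in
  `(onset, onset + 50.5]`; this partitions each run exactly (segments of
  51 and 50 TRs alternating, totalling 313) with no TR claimed twice. The
  per-TR probe SF is the level occupying the majority of that TR's ten
  frames, ties resolved toward the earlier-onset level. The 1 s cue and
  the 30 ms cue–block gap carry no probe stimulus and are absorbed into
  the preceding blank.

## Forward model

The SF response is a Gaussian in natural-log SF,
`R(f) = exp(−(ln f − ln μ)²/(2σ²))`, maximal (1) at the preferred SF μ.
σ is applied to log-SF differences and is reported unconverted (it is not
a linear-frequency half-width). Blanks carry a sentinel SF of 0.0001 cpd
rather than being masked; for realistic tunings (μ ≳ 0.1 cpd, σ ≲ 2) the
sentinel response is numerically zero, but note it is *not* negligible in
the far corner of the parameter box (μ near 0.009 with σ near 4 gives
R(sentinel) ≈ 0.5) — estimates in that corner should be treated as
degenerate, and the selection stage's μ ≥ 0.01 floor removes them.

The hemodynamic impulse response is a gamma density with shape `n = 3`,
scale `τ = 1.08` s, shifted by an onset delay of 2.05 s (the printed form
reuses one symbol for the running time and the fixed delay; it is
interpreted here as a Boynton-style gamma evaluated at `t − 2.05`, which
reproduces the intended peak at `2.05 + (n−1)τ = 4.21` s). The kernel is
sampled at TR midpoints over a 32 s window (≥ 99.9% of its mass) and the
prediction is the causal discrete convolution truncated to the input
length, `B(t) = β₀ + β·(R∗h)(t)`. Convolution at TR rather than frame
(0.1 s) resolution matches the resolution of the measured series; a finer
`tr` can be passed through `PSFTRegressor`/`hirf_kernel` if wanted.

## Estimation

Per voxel and condition, the matching blocks (each plus its trailing
blank) are concatenated across runs in run order, and the SF track is
spliced identically. Fitting is a three-stage pipeline:

1. **Coarse grid** — 10 log-spaced μ over [0.009, 6] × 10 linear σ over
   [0.1, 4], with β = 1, β₀ = 0 fixed; lowest SSE wins.
2. **Fine grid** — 100 × 100 between half and double the coarse optimum,
   clipped to the global bounds, β/β₀ fixed as before. Exact SSE ties
   (after rounding to 12 significant digits, so floating-point noise does
   not suppress the rule) are resolved by averaging the tied parameter
   values.
3. **Bounded least squares** over (μ, σ, β, β₀) from the fine-grid start
   (scipy's trust-region reflective method), bounds as above plus
   β ∈ [−25, 25], β₀ ∈ [−10, 10]. The returned fit never has SSE above
   the initializer's; an optimizer failure or regression returns the
   initializer flagged `converged=False`.

Tolerances default to 1e-10 on `ftol`/`xtol`/`gtol` with at most 2,500
residual evaluations, both configurable. The tight default costs little
(the problem has 4 parameters) and lets noiseless simulations recover
parameters to near machine precision, which the end-to-end recovery tests
rely on. Fitting is fully deterministic.

R² is the coefficient of determination, `100·(1 − SSE/TSS)` with TSS about
the mean of the measured series: negative when the fit is worse than the
mean, defined as 0 (with a warning) for a zero-variance series. Raw
intensity series can be converted to percent signal change with
`percent_signal_change`, normalizing by the mean over blank TRs (grand
mean if no blanks are flagged); series that are already percent signal
change — including all synthetic series — are fitted as-is.

## Voxel selection

Criteria are applied as printed, with interval phrasing resolved once:
"within"/"between" ranges are closed ([0.16, 9.8]° eccentricity,
μ ∈ [0.01, 5] cpd, σ ∈ [0.10, 4]), ">" thresholds are strict (size
> 0.1°, both R² > 10%). Polar-angle wedges are open intervals; the
right-hemifield window (280° < θ < 80°) wraps through 0°. A voxel must
pass the pSFT criteria in *all* conditions present (a per-condition switch
exists), since the modulation indices need valid estimates on both sides.
The 3-SD screen on μ and σ is computed once per
(subject ×) ROI × condition group (sample SD; single-voxel groups are kept
with a warning) and a voxel flagged anywhere is dropped everywhere —
making the whole cascade idempotent and order-independent.

## Attention statistics

`AMI(%) = 100·(A − B)/(A + B)` with A the attention-condition estimate and
B the attend-fixation baseline, so negative peak-AMI means a downward
shift of the preferred SF. Dissimilarity is `log₂(μ_baseline/0.5)` toward
the low attended SF and `log₂(μ_baseline/2.0)` toward the high one (the
two differ by exactly 2 octaves). Per subject, ROI and condition a
first-degree polynomial relates dissimilarity (or a pRF attribute) to AMI
via ordinary least squares. Group inference: one-sample and paired t
tests on subject-level values, Bonferroni-corrected with the family
defaulting to the three tests of one panel (within-LSF, within-HSF,
LSF-vs-HSF); one-way ANOVA across the three conditions for task-level
metrics; Cohen's d (one-sample `mean/SD`, paired on differences) with a
2.5/97.5-percentile CI over 1,000 seeded resamples; the minimum
detectable effect solves noncentral-t power for d (1.156 at n = 8,
α = 0.05, power = 0.80). The repeated-measures correlation delegates to
pingouin's ANCOVA formulation (df = N − k − 1; at least 3 subjects),
verified on constructed Simpson's-paradox cases. Subject means enter the
group tests unweighted by voxel count, and no second outlier screen is
applied to AMIs.

## Synthetic data

The generator emulates the study conditions, not scanner physics:

- **Population trends.** Baseline peaks follow `ln μ = a − b·ecc` with
  ROI-specific intercepts/slopes (lower and steeper from V1 to V3),
  lognormal scatter (SD 0.25 in log), clipped to [0.12, 3.5] cpd so
  shifted parameters stay strictly inside the optimizer box; bandwidths
  rise linearly with eccentricity and area, clipped to [0.3, 3.0].
  Eccentricities are uniform over the probe aperture [0.16, 9.8]°, polar
  angles uniform in the hemifield wedge; β ∈ [0.8, 1.5],
  β₀ ∈ [−0.3, 0.3]. The magnitudes parameterize the qualitative trends
  (they are configuration, not measured fact).
- **Attention shifts.** Condition parameters are the generative inverse of
  a target AMI slope: `A = B·(100 + s·Δ)/(100 − s·Δ)` with Δ the octave
  dissimilarity, so the analysis' AMI-vs-dissimilarity slope equals the
  configured `s` exactly on noiseless data. Defaults: peak −10 %/octave
  (attractive), bandwidth +3 %/octave. Out-of-bounds shifts are clipped
  and flagged.
- **Noise.** I.i.d. Gaussian on the predicted percent signal change, with
  per-voxel SD set as `sd(signal)·√((1−R²)/R²)` for a target expected fit
  R² (default 0.40, inside the plausible 30–60% regime above the 10%
  selection floor; per-voxel noise levels are not otherwise published).
- **Splice-level generation.** Series are generated per condition on the
  session-spliced SF track (one convolution over the concatenated
  blocks), i.e. at exactly the level the estimator consumes. This makes
  the generative and fitting models coincide — the hemodynamic response
  is implicitly assumed to have returned to baseline within each 10 s
  blank, which the ~11 s 99%-mass of the HIRF only approximately
  guarantees for real runs. Consequently the recovery tests validate the
  estimation machinery, not robustness to cross-block bleed-over, drift,
  physiological or temporally correlated noise (an AR(1) option is a
  natural extension and deliberately off by default since the fitted
  model assumes none).

Problem sizes in the end-to-end tests are desk-scale choices: the
oracle-equivalence check runs 20 voxels over three-run sessions against a
400×400 exhaustive grid with closed-form (β, β₀) per cell; parameter
recovery uses 200 voxels over the full nine-run session; slope recovery
uses eight subjects (the study's n) with 16 voxels each (noisy) and 6
each (noiseless), over three-run sessions.

## Stimulus filtering

Stimulus images are band-limited by multiplying the centered 2D FFT with
a circularly symmetric radial filter, smoothed with a Gaussian (SD
3 pixels for letters, ppd/10 for noise carriers) and min-max normalized
to [0, 1]; letter images are complemented first. The filtered image is
re-normalized (by its range for letters, its maximum for noise),
rectified, scaled by 127 and offset by 127, then clipped to [0, 255]
(clipping is logged; with the default normalization it cannot trigger,
but custom radial profiles may overshoot). Frequencies are specified in
cycles/degree with an explicit pixels-per-degree parameter (Nyquist =
ppd/2 cpd) and converted to cycles/pixel internally. The exact radial
profile of the original filter is not published; the default is a
difference-of-discs annulus `[center·(1−w), center·(1+w)]` with w = 0.2 —
an approximation, exposed as a pluggable callable for users who need a
different profile.

## Known limitations

- pRF attributes are simulated or ingested, never estimated.
- No detrending or high-pass filtering is applied before fitting (none is
  assumed by the generative model either).
- The estimator is a local refinement of a finite grid: global-optimality
  is checked statistically against the exhaustive-grid oracle, not
  guaranteed per voxel.
- Dissimilarity uses the *fitted* baseline peak on real and noisy data;
  its estimation error is shared with the AMI numerator, which can bias
  fitted slopes slightly negative at low SNR (visible as a small
  attraction-like component). The CI-coverage test bounds this effect at
  the default noise level but it should be kept in mind when SNR is poor.
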