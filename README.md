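# psft

Voxel-wise **population spatial-frequency tuning (pSFT)** estimation and
attentional-modulation analysis for block-design fMRI, with a synthetic-data
generator that makes the whole pipeline testable at desk scale.

## The problem

Neural populations in early visual cortex (V1–V3) are tuned to spatial
frequency (SF): each fMRI voxel responds maximally to a preferred SF and
progressively less to frequencies away from it. When observers deploy
feature-based attention to a particular SF (for instance, one of two
superimposed letter streams defined by low- vs high-SF content), the tuning
of populations across the visual field can shift toward the attended
frequency. This package implements the model-based analysis that measures
those tunings and shifts from BOLD time series:

- **Forward model.** A voxel's response to the probe frequency `f(t)` is a
  Gaussian in log-SF,

  `R(f) = exp(−(log f − log μ)² / (2σ²))`,

  with preferred SF `μ` (cpd) and bandwidth `σ`. The predicted BOLD percent
  signal change is `B(t) = β₀ + β·(R[f(t)] ∗ h)(t)` where `h` is a gamma
  hemodynamic impulse response (time constant τ = 1.08 s, phase delay
  n = 3, onset delay 2.05 s). Blank periods carry a sentinel SF of 0.0001
  cpd so `R ≈ 0` there.
- **Estimation.** Per voxel and attention condition, matching task blocks
  (each with its trailing 10 s blank) are spliced across runs; `(μ, σ, β, β₀)`
  are then estimated by a 10×10 coarse grid, a 100×100 fine grid between
  half and double the coarse optimum, and bounded nonlinear least squares,
  minimizing the sum of squared errors within
  μ ∈ [0.009, 6], σ ∈ [0.1, 4], β ∈ [−25, 25], β₀ ∈ [−10, 10].
- **Selection.** pRF-based criteria (eccentricity 0.16–9.8°, size > 0.1°,
  polar angle inside the probe wedge, pRF R² > 10%) and pSFT-based criteria
  (R² > 10%, μ ∈ [0.01, 5] cpd, σ ∈ [0.10, 4]), then a single-pass 3-SD
  outlier screen on μ and σ per ROI × condition.
- **Attention statistics.** The attentional modulation index
  `AMI(%) = 100·(A − B)/(A + B)` compares each parameter under attention
  (A) against the attend-fixation baseline (B); AMIs are regressed on the
  octave dissimilarity `log₂(μ_baseline / SF_attended)` per subject, with
  group-level t tests, Bonferroni correction, bootstrap Cohen's d
  (1,000 resamples) and repeated-measures correlations.

The synthetic-data module generates voxel populations with the canonical
eccentricity trends (peak falls, bandwidth rises with eccentricity and up
the visual hierarchy), condition-dependent attractive shifts constructed so
that `AMI = slope × dissimilarity` exactly, and calibrated Gaussian noise —
so parameter- and slope-recovery are verifiable end to end.

## Worked example

```python
import numpy as np
from psft import (build_run_design, build_session_schedule,
                  build_probe_sf_sequence, concatenate_condition_blocks,
                  predict_bold, PSFTParams, PSFTRegressor)

# a three-run session of the default timeline (313 TRs per run)
runs = build_session_schedule(3, build_run_design(seed=1), seed=3)
seqs = [build_probe_sf_sequence(r, seed=10 + i) for i, r in enumerate(runs)]

# splice the attend-fixation blocks and synthesize a noisy voxel
spliced = concatenate_condition_blocks(
    [(None, r, s) for r, s in zip(runs, seqs)], "AttendFixation")
truth = PSFTParams(mu=1.3, sigma=0.9, beta=1.2, beta0=0.1)
rng = np.random.default_rng(0)
bold = predict_bold(spliced.sf_per_tr, truth) + rng.normal(0, 0.3, spliced.sf_per_tr.size)

est = PSFTRegressor().fit(spliced.sf_per_tr, bold)
print(f"mu = {est.mu_:.3f} cpd, sigma = {est.sigma_:.3f}, R2 = {est.r2_:.1f}%")
```

prints

```
mu = 1.412 cpd, sigma = 0.918, R2 = 38.2%
```

i.e. the voxel's preferred SF is recovered near the generating 1.3 cpd with
bandwidth near 0.9, and the model explains ~38% of the variance of this
noisy series (with no noise the recovery is exact and R² = 100%). A
command-line interface mirrors the library:

```bash
psft design   --n-runs 9 --seed 1 --out design/
psft simulate --n-subjects 8 --n-voxels 50 --seed 1 --out sim/
psft fit      --voxels sim/voxels.tsv --series sim/series.tsv \
              --sf-tracks sim/sf_tracks.tsv --out fits.tsv
psft analyze  --fits fits.tsv --voxels sim/voxels.tsv --out report/
```

## Layout

| module | contents |
|---|---|
| `psft.design` | run/session timelines, probe SF sequence (40 log-spaced SFs, 0.1–12 cpd) |
| `psft.stimgen` | 2D FFT bandpass filtering of stimulus images |
| `psft.model` | log-Gaussian SF response, gamma HIRF, BOLD prediction |
| `psft.simulate` | ground-truth voxel populations, attention shifts, noisy series |
| `psft.fitting` | block splicing, grid searches, `PSFTRegressor` |
| `psft.selection` | pRF/pSFT criteria and the 3-SD outlier screen |
| `psft.stats` | AMI, dissimilarity, slopes, effect sizes, group tests |

See `docs/methods.md` for modeling assumptions, numerical choices and
limitations.
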