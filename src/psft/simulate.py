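"""Synthetic voxel populations with known ground-truth tuning.

Emulates the study conditions at desk scale: V1-V3 voxels whose baseline
tuning peak falls and bandwidth rises with pRF eccentricity, condition
dependent attractive shifts toward the attended SF (constructed so the
attentional modulation index is exactly ``slope x octave-dissimilarity``),
and additive Gaussian measurement noise on the predicted BOLD.

Because the estimation stage consumes condition-spliced series (matching
blocks concatenated across runs, then a single convolution), time series
are generated at that same splice level: the generative and fitting models
then coincide exactly, which is what makes noiseless parameter and slope
recovery a meaningful end-to-end check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    ATTENDED_SF,
    CONDITIONS,
    RunDesign,
    SFSequence,
    build_probe_sf_sequence,
    build_run_design,
    build_session_schedule,
)
from .fitting import concatenate_condition_blocks
from .model import MU_BOUNDS, SIGMA_BOUNDS, HIRFSpec, PSFTParams, hirf_kernel, predict_bold

ROIS = ("V1", "V2", "V3")

#: Baseline tuning trends per ROI: log mu = a - b * eccentricity, with the
#: intercept lower and the eccentricity fall-off steeper from V1 to V3, and
#: bandwidth sigma = c0 + c1 * eccentricity rising with eccentricity and
#: area.  These span roughly 0.25-3 cpd over the probe aperture.
_ROI_TRENDS = {
    #        a (log cpd)      b (/deg)  c0    c1
    "V1": (np.log(3.2), 0.18, 0.9, 0.06),
    "V2": (np.log(2.7), 0.20, 1.1, 0.07),
    "V3": (np.log(2.2), 0.22, 1.3, 0.08),
}

ECC_RANGE = (0.16, 9.8)  # probe aperture, degrees
_POLAR_WEDGE = {"left": (100.0, 260.0), "right": (280.0, 80.0)}


@dataclass
class ShiftModel:
    """Attentional shift as the generative inverse of a measured AMI slope.

    ``peak_slope`` / ``bandwidth_slope`` are AMI-percent per octave of
    dissimilarity between the baseline peak and the attended SF; negative
    peak slope = attractive shift toward the attended SF.
    """

    peak_slope: float = -10.0
    bandwidth_slope: float = 3.0
    attended_sf: dict = field(default_factory=lambda: dict(ATTENDED_SF))


@dataclass
class GroundTruthVoxel:
    voxel_id: int
    roi: str
    prf_ecc: float
    prf_polar: float
    prf_size: float
    prf_r2: float
    params_by_condition: dict[str, PSFTParams]
    noise_sd: float | None = None
    subject: int = 0
    clipped: bool = False  # an attention shift escaped the bounds box


def _ami_to_ratio(ami_percent: float) -> float:
    """Invert AMI = 100 (A - B)/(A + B) for A/B."""
    if not -100 < ami_percent < 100:
        raise ValueError("AMI inversion requires |AMI| < 100")
    return (100.0 + ami_percent) / (100.0 - ami_percent)


def apply_attention_shift(
    voxel: GroundTruthVoxel | PSFTParams,
    condition: str,
    model: ShiftModel,
) -> PSFTParams:
    """Condition parameters such that AMI(condition vs baseline) equals
    ``slope x dissimilarity`` exactly, for both peak and bandwidth.

    Shifted values escaping the optimizer bounds are clipped (flagged on
    the voxel when one is passed).
    """
    if isinstance(voxel, GroundTruthVoxel):
        base = voxel.params_by_condition["AttendFixation"]
    else:
        base = voxel
    if condition == "AttendFixation":
        return base
    att = model.attended_sf[condition]
    dissim = np.log2(base.mu / att)
    mu = base.mu * _ami_to_ratio(model.peak_slope * dissim)
    sigma = base.sigma * _ami_to_ratio(model.bandwidth_slope * dissim)
    mu_c = float(np.clip(mu, *MU_BOUNDS))
    sigma_c = float(np.clip(sigma, *SIGMA_BOUNDS))
    if (mu_c != mu or sigma_c != sigma) and isinstance(voxel, GroundTruthVoxel):
        voxel.clipped = True
    return replace(base, mu=mu_c, sigma=sigma_c)


def sample_population(
    n_voxels: int,
    roi_mix: dict[str, float] | None = None,
    seed: int = 0,
    hemifield: str = "left",
    shift_model: ShiftModel | None = None,
    subject: int = 0,
) -> list[GroundTruthVoxel]:
    """Draw a seeded voxel population with eccentricity-dependent tuning.

    Baseline peaks follow a log-linear decline with eccentricity and
    bandwidths a linear rise, both ROI-dependent (`_ROI_TRENDS`), plus
    lognormal/Gaussian scatter; condition parameters are derived through
    `apply_attention_shift`.
    """
    roi_mix = roi_mix or {r: 1 / 3 for r in ROIS}
    if abs(sum(roi_mix.values()) - 1) > 1e-9:
        raise ValueError("roi_mix proportions must sum to 1")
    model = shift_model or ShiftModel()
    rng = np.random.default_rng(seed)
    rois = rng.choice(list(roi_mix), size=n_voxels, p=list(roi_mix.values()))
    lo, hi = _POLAR_WEDGE[hemifield]
    voxels = []
    for i in range(n_voxels):
        roi = str(rois[i])
        a, b, c0, c1 = _ROI_TRENDS[roi]
        ecc = rng.uniform(*ECC_RANGE)
        if hemifield == "left":
            polar = rng.uniform(lo, hi)
        else:  # wraps through 0/360
            polar = (rng.uniform(lo, lo + (360 - lo) + hi)) % 360
        mu = float(np.exp(a - b * ecc + rng.normal(0, 0.25)))
        mu = float(np.clip(mu, 0.12, 3.5))
        sigma = float(np.clip(c0 + c1 * ecc + rng.normal(0, 0.15), 0.3, 3.0))
        base = PSFTParams(
            mu=mu,
            sigma=sigma,
            beta=float(rng.uniform(0.8, 1.5)),
            beta0=float(rng.uniform(-0.3, 0.3)),
        )
        vox = GroundTruthVoxel(
            voxel_id=i,
            roi=roi,
            prf_ecc=ecc,
            prf_polar=float(polar),
            prf_size=float(max(0.15 + 0.2 * ecc + rng.normal(0, 0.1), 0.11)),
            prf_r2=float(rng.uniform(15, 90)),
            params_by_condition={"AttendFixation": base},
            subject=subject,
        )
        for cond in ("AttendLSF", "AttendHSF"):
            vox.params_by_condition[cond] = apply_attention_shift(vox, cond, model)
        voxels.append(vox)
    return voxels


def noise_sd_for_target_r2(signal: np.ndarray, target_r2: float = 0.40) -> float:
    """Gaussian noise SD giving expected variance-explained ``target_r2``
    for a noiseless signal: sd = std(signal) * sqrt((1 - r2) / r2)."""
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    s = float(np.std(signal))
    return s * np.sqrt((1 - target_r2) / target_r2)


def simulate_timeseries(
    voxel: GroundTruthVoxel,
    condition: str,
    design: RunDesign | list[RunDesign],
    sfseq: SFSequence | list[SFSequence],
    seed: int = 0,
    hirf: HIRFSpec | None = None,
) -> np.ndarray:
    """Noisy condition-spliced BOLD series for one voxel.

    Splices the condition's blocks (plus trailing blanks) across the given
    run(s), evaluates the forward model on the spliced SF track, and adds
    i.i.d. Gaussian noise of ``voxel.noise_sd`` (0 => noiseless).
    """
    designs = design if isinstance(design, list) else [design]
    sfseqs = sfseq if isinstance(sfseq, list) else [sfseq]
    if len(designs) != len(sfseqs):
        raise ValueError("design and sfseq lists misaligned")
    for d, s in zip(designs, sfseqs):
        if s.sf_per_tr.size != d.n_trs:
            raise ValueError("sfseq length does not match design")
    spliced = concatenate_condition_blocks(
        [(None, d, s) for d, s in zip(designs, sfseqs)], condition
    )
    kernel = hirf_kernel(hirf or HIRFSpec(), tr=designs[0].tr_seconds)
    pred = predict_bold(
        spliced.sf_per_tr, voxel.params_by_condition[condition], kernel=kernel
    )
    sd = voxel.noise_sd or 0.0
    if sd == 0:
        return pred
    rng = np.random.default_rng(seed)
    return pred + rng.normal(0, sd, size=pred.size)


@dataclass
class SyntheticStudy:
    """A full simulated experiment: per-subject sessions plus ground truth."""

    voxels: list[GroundTruthVoxel]
    designs: dict[int, list[RunDesign]]  # subject -> runs
    sfseqs: dict[int, list[SFSequence]]
    sf_tracks: dict[tuple[int, str], np.ndarray]  # (subject, condition) -> spliced SF
    series: dict[tuple[int, int, str], np.ndarray]  # (subject, voxel, condition)
    seed: int

    def voxels_table(self) -> pd.DataFrame:
        rows = []
        for v in self.voxels:
            row = {
                "subject": v.subject,
                "voxel_id": v.voxel_id,
                "roi": v.roi,
                "prf_ecc": v.prf_ecc,
                "prf_polar": v.prf_polar,
                "prf_size": v.prf_size,
                "prf_r2": v.prf_r2,
                "noise_sd": v.noise_sd,
                "clipped": v.clipped,
            }
            for cond, p in v.params_by_condition.items():
                row[f"true_mu_{cond}"] = p.mu
                row[f"true_sigma_{cond}"] = p.sigma
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_study(
    n_subjects: int = 8,
    n_voxels: int = 50,
    n_runs: int = 9,
    seed: int = 0,
    shift_model: ShiftModel | None = None,
    target_r2: float | None = 0.40,
    hemifield: str = "left",
    hirf: HIRFSpec | None = None,
) -> SyntheticStudy:
    """Simulate a whole experiment.

    Each subject gets an independently seeded session (run schedules and
    probe sequences) and ``n_voxels`` ground-truth voxels.  Per voxel, the
    noise SD is set from the noiseless baseline-condition signal so the
    expected fit R^2 is ``target_r2`` (None => noiseless).
    """
    model = shift_model or ShiftModel()
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    voxels: list[GroundTruthVoxel] = []
    designs: dict[int, list[RunDesign]] = {}
    sfseqs: dict[int, list[SFSequence]] = {}
    sf_tracks: dict[tuple[int, str], np.ndarray] = {}
    series: dict[tuple[int, int, str], np.ndarray] = {}

    for s in range(n_subjects):
        ints = subj_seeds[s].generate_state(4)
        runs = build_session_schedule(
            n_runs, build_run_design(seed=int(ints[0] % 2**31)), seed=int(ints[0] % 2**31)
        )
        seqs = [
            build_probe_sf_sequence(d, seed=int((ints[1] + i) % 2**31))
            for i, d in enumerate(runs)
        ]
        designs[s], sfseqs[s] = runs, seqs
        pop = sample_population(
            n_voxels,
            seed=int(ints[2] % 2**31),
            hemifield=hemifield,
            shift_model=model,
            subject=s,
        )
        kernel = hirf_kernel(hirf or HIRFSpec(), tr=runs[0].tr_seconds)
        for cond in CONDITIONS:
            spliced = concatenate_condition_blocks(
                [(None, d, q) for d, q in zip(runs, seqs)], cond
            )
            sf_tracks[(s, cond)] = spliced.sf_per_tr
        noise_rng = np.random.default_rng(int(ints[3] % 2**31))
        for v in pop:
            base_signal = predict_bold(
                sf_tracks[(s, "AttendFixation")],
                v.params_by_condition["AttendFixation"],
                kernel=kernel,
            )
            v.noise_sd = (
                0.0 if target_r2 is None else noise_sd_for_target_r2(base_signal, target_r2)
            )
            for cond in CONDITIONS:
                pred = predict_bold(
                    sf_tracks[(s, cond)], v.params_by_condition[cond], kernel=kernel
                )
                if v.noise_sd:
                    pred = pred + noise_rng.normal(0, v.noise_sd, size=pred.size)
                series[(s, v.voxel_id, cond)] = pred
        voxels.extend(pop)

    n_clipped = sum(v.clipped for v in voxels)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} voxels had attention-shifted parameters clipped to bounds",
            stacklevel=2,
        )
    return SyntheticStudy(voxels, designs, sfseqs, sf_tracks, series, seed)
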