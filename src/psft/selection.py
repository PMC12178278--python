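"""Voxel inclusion criteria.

Two independent screens: pRF-based (eccentricity, size, polar-angle wedge,
pRF fit quality — decided before any pSFT fit, avoiding circular
selection) and pSFT-based (fit quality, parameter ranges), followed by a
single-pass 3-SD outlier exclusion of ``mu``/``sigma`` within each
(subject,) ROI x condition group.

Endpoint conventions (the source phrasing mixes "within" and ">"):
ranges stated as "between"/"within" are closed intervals; thresholds
stated with ">" are strict.  The right-hemifield polar window wraps
through 0/360.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionCriteria:
    ecc_range: tuple[float, float] = (0.16, 9.8)  # degrees, closed
    min_prf_size: float = 0.1  # degrees diameter, strict >
    polar_windows: dict = field(
        default_factory=lambda: {"left": (100.0, 260.0), "right": (280.0, 80.0)}
    )
    min_prf_r2: float = 10.0  # percent, strict >
    min_psft_r2: float = 10.0  # percent, strict >
    mu_range: tuple[float, float] = (0.01, 5.0)  # cpd, closed
    sigma_range: tuple[float, float] = (0.10, 4.0)  # closed
    outlier_sd: float = 3.0


def in_polar_window(theta, window: tuple[float, float]) -> np.ndarray:
    """Strict open wedge membership; windows with lo > hi wrap through 0."""
    theta = np.asarray(theta, float) % 360
    lo, hi = window
    if lo < hi:
        return (theta > lo) & (theta < hi)
    return (theta > lo) | (theta < hi)


def apply_prf_criteria(
    voxels: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    hemifield: str = "left",
) -> pd.DataFrame:
    """Keep voxels satisfying all four pRF conditions."""
    c = criteria or SelectionCriteria()
    required = {"prf_ecc", "prf_polar", "prf_size", "prf_r2"}
    missing = required - set(voxels.columns)
    if missing:
        raise ValueError(f"voxels table missing columns: {sorted(missing)}")
    keep = (
        (voxels["prf_ecc"] >= c.ecc_range[0])
        & (voxels["prf_ecc"] <= c.ecc_range[1])
        & (voxels["prf_size"] > c.min_prf_size)
        & (voxels["prf_r2"] > c.min_prf_r2)
        & in_polar_window(voxels["prf_polar"], c.polar_windows[hemifield])
    )
    return voxels[keep]


def apply_psft_criteria(
    fits: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    require_all_conditions: bool = True,
) -> pd.DataFrame:
    """Keep fits with pSFT R^2 above threshold and mu/sigma in range.

    With ``require_all_conditions`` (default), a voxel survives only if
    every condition present in the input passes — the modulation indices
    need a valid estimate in baseline and attention conditions alike.
    """
    c = criteria or SelectionCriteria()
    if fits.empty:
        return fits
    ok = (
        (fits["r2"] > c.min_psft_r2)
        & (fits["mu"] >= c.mu_range[0])
        & (fits["mu"] <= c.mu_range[1])
        & (fits["sigma"] >= c.sigma_range[0])
        & (fits["sigma"] <= c.sigma_range[1])
    )
    passed = fits[ok]
    if not require_all_conditions:
        return passed
    keys = ["subject", "voxel_id"] if "subject" in fits.columns else ["voxel_id"]
    n_cond = fits["condition"].nunique()
    counts = passed.groupby(keys)["condition"].nunique()
    full = counts[counts == n_cond].index
    idx = pd.MultiIndex.from_frame(passed[keys]) if len(keys) > 1 else passed[keys[0]]
    return passed[idx.isin(full)]


def exclude_outliers(
    fits: pd.DataFrame,
    group_keys: list[str] | None = None,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Single-pass 3-SD screen on ``mu`` and ``sigma``.

    A voxel flagged in ANY of its groups is dropped from every condition.
    Group means/SDs (sample SD, ddof=1) are computed once on the input;
    size-1 groups (SD undefined) are kept with a warning.
    """
    if fits.empty:
        return fits
    if group_keys is None:
        group_keys = (["subject"] if "subject" in fits.columns else []) + [
            "roi",
            "condition",
        ]
    voxel_keys = (["subject"] if "subject" in fits.columns else []) + ["voxel_id"]
    g = fits.groupby(group_keys)
    if (g.size() == 1).any():
        warnings.warn("size-1 group(s): SD undefined, voxels kept", stacklevel=2)
    flagged = pd.Series(False, index=fits.index)
    for col in ("mu", "sigma"):
        mean = g[col].transform("mean")
        sd = g[col].transform("std")  # ddof=1; NaN for size-1 groups
        with np.errstate(invalid="ignore"):
            flagged |= ((fits[col] - mean).abs() > k_sd * sd).fillna(False)
    bad = fits.loc[flagged, voxel_keys].drop_duplicates()
    merged = fits.merge(bad.assign(_bad=True), on=voxel_keys, how="left")
    return fits[merged["_bad"].isna().to_numpy()]


def select_voxels(
    voxels: pd.DataFrame,
    fits: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    hemifield: str = "left",
) -> tuple[pd.DataFrame, dict]:
    """Full selection cascade; returns surviving fits and an attrition log."""
    c = criteria or SelectionCriteria()
    voxel_keys = (["subject"] if "subject" in fits.columns else []) + ["voxel_id"]

    def n_voxels(df):
        return len(df[voxel_keys].drop_duplicates())

    log = {"input": n_voxels(fits)}
    prf_ok = apply_prf_criteria(voxels, c, hemifield)
    fits1 = fits.merge(prf_ok[voxel_keys], on=voxel_keys)
    log["after_prf"] = n_voxels(fits1)
    fits2 = apply_psft_criteria(fits1, c)
    log["after_psft"] = n_voxels(fits2)
    fits3 = exclude_outliers(fits2, k_sd=c.outlier_sd)
    log["after_outlier"] = n_voxels(fits3)
    log["survival_fraction"] = log["after_outlier"] / max(log["input"], 1)
    return fits3, log
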