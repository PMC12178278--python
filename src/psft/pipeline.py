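"""End-to-end glue: fit a simulated (or ingested) study and analyze it."""

from __future__ import annotations

import pandas as pd

from .fitting import PSFTRegressor
from .selection import SelectionCriteria, select_voxels
from .simulate import SyntheticStudy
from .stats import build_modulation_table, condition_contrasts, subject_slopes


def fit_voxel_set(
    series: dict,
    sf_tracks: dict,
    meta: pd.DataFrame | None = None,
    **regressor_kw,
) -> pd.DataFrame:
    """Fit every (subject, voxel, condition) series; returns a tidy table.

    ``series`` maps ``(subject, voxel_id, condition)`` to a spliced BOLD
    series and ``sf_tracks`` maps ``(subject, condition)`` to the matching
    spliced SF track.  ``meta`` (optional, indexed like a voxels table)
    contributes per-voxel columns such as ``roi`` to the output.
    """
    meta_idx = None
    if meta is not None:
        keys = ["subject", "voxel_id"] if "subject" in meta.columns else ["voxel_id"]
        meta_idx = meta.set_index(keys)
    rows = []
    for (subject, voxel_id, condition), y in sorted(series.items()):
        sf = sf_tracks[(subject, condition)]
        est = PSFTRegressor(**regressor_kw).fit(sf, y)
        row = {
            "subject": subject,
            "voxel_id": voxel_id,
            "condition": condition,
            "mu": est.mu_,
            "sigma": est.sigma_,
            "beta": est.beta_,
            "beta0": est.beta0_,
            "sse": est.sse_,
            "r2": est.r2_,
            "converged": est.converged_,
        }
        if meta_idx is not None:
            key = (subject, voxel_id) if "subject" in meta_idx.index.names else voxel_id
            if key in meta_idx.index:
                info = meta_idx.loc[key]
                for col in ("roi", "prf_ecc", "prf_polar", "prf_size", "prf_r2"):
                    if col in info.index:
                        row[col] = info[col]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_study(study: SyntheticStudy, **regressor_kw) -> pd.DataFrame:
    return fit_voxel_set(
        study.series, study.sf_tracks, study.voxels_table(), **regressor_kw
    )


def analyze_fits(
    fits: pd.DataFrame,
    voxels: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    hemifield: str = "left",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Selection -> modulation table -> subject slopes -> group statistics."""
    selected, attrition = select_voxels(voxels, fits, criteria, hemifield)
    modulation = build_modulation_table(selected)
    slope_tables = []
    for outcome in ("ami_peak", "ami_bandwidth"):
        slope_tables.append(subject_slopes(modulation, "dissimilarity", outcome))
    slopes = pd.concat(slope_tables, ignore_index=True)
    contrasts = condition_contrasts(
        slopes.rename(columns={"slope": "value"}),
        by=("roi", "outcome"),
        n_boot=n_boot,
        seed=seed,
    )
    return {
        "selected": selected,
        "attrition": attrition,
        "modulation": modulation,
        "slopes": slopes,
        "slope_contrasts": contrasts,
    }
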