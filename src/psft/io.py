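"""Plain-text table serialization (TSV + JSON manifests)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import RunDesign, SFSequence


def design_table(design: RunDesign, sfseq: SFSequence, run: int = 0) -> pd.DataFrame:
    """One row per TR: run, time, block index, condition, probe SF."""
    block_idx = np.full(design.n_trs, -1)
    cond = np.array(["blank"] * design.n_trs, dtype=object)
    for b in range(design.n_blocks):
        sl = design.block_tr_slice(b)
        block_idx[sl] = b
        cond[sl] = design.condition_per_block[b]
    return pd.DataFrame(
        {
            "run": run,
            "t": np.arange(design.n_trs) * design.tr_seconds,
            "block_index": block_idx,
            "condition": cond,
            "sf_cpd": sfseq.sf_per_tr,
        }
    )


def write_design(designs, sfseqs, out_dir, params: dict | None = None) -> None:
    """Write per-TR design tables and a JSON sidecar of generation params."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = [design_table(d, s, run=i) for i, (d, s) in enumerate(zip(designs, sfseqs))]
    pd.concat(tables, ignore_index=True).to_csv(out / "design.tsv", sep="\t", index=False)
    if params is not None:
        (out / "design.json").write_text(json.dumps(params, indent=2, default=str))


def write_series(series: dict, out_path) -> None:
    """Per-condition series matrices: one row per voxel, TRs as columns.

    ``series`` maps ``(subject, voxel_id, condition)`` to a 1-d array.
    """
    rows = []
    for (subject, voxel_id, condition), y in sorted(series.items()):
        rows.append(
            {"subject": subject, "voxel_id": voxel_id, "condition": condition}
            | {f"t{i}": v for i, v in enumerate(np.asarray(y))}
        )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


def _trim_padding(values: np.ndarray, where: str) -> np.ndarray:
    """Strip the trailing-NaN padding rows acquire in a ragged wide table."""
    nan = np.isnan(values)
    if not nan.any():
        return values
    first = int(np.argmax(nan))
    if not nan[first:].all():
        raise ValueError(f"interior NaNs in {where}")
    return values[:first]


def read_series(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    out = {}
    for _, row in df.iterrows():
        key = (row["subject"], row["voxel_id"], row["condition"])
        out[key] = _trim_padding(row[tcols].to_numpy(dtype=float), str(key))
    return out


def write_sf_tracks(sf_tracks: dict, out_path) -> None:
    """Spliced SF tracks, one row per (subject, condition)."""
    rows = []
    for (subject, condition), sf in sorted(sf_tracks.items()):
        rows.append(
            {"subject": subject, "condition": condition}
            | {f"t{i}": v for i, v in enumerate(np.asarray(sf))}
        )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


def read_sf_tracks(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    tcols = sorted(
        (c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return {
        (row["subject"], row["condition"]): _trim_padding(
            row[tcols].to_numpy(dtype=float), str((row["subject"], row["condition"]))
        )
        for _, row in df.iterrows()
    }


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
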