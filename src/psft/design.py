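"""Experiment timeline and probe spatial-frequency sequence construction.

A session consists of task runs, each an initial blank followed by task
blocks (one attention condition per block) separated by blanks.  The
task-irrelevant hemifield shows a pseudorandom stream of SF-bandlimited
noise probes whose center spatial frequencies are log-spaced; the model
consumes one SF value per TR, with a small sentinel SF coding blanks so
the log-Gaussian response is effectively zero there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Task conditions: attend the low-SF letter stream (0.5 cpd), the high-SF
#: stream (2 cpd), or the fixation luminance task (baseline).
CONDITIONS = ("AttendLSF", "AttendHSF", "AttendFixation")

#: Sentinel spatial frequency carried by blank TRs/frames (avoids log(0)).
BLANK_SF = 1e-4

#: Attended center SF (cpd) per attention condition.
ATTENDED_SF = {"AttendLSF": 0.5, "AttendHSF": 2.0}

_FRAME_S = 0.1  # stimulus refresh granularity used for timing validation


@dataclass(frozen=True)
class RunDesign:
    """Per-run timeline: block onsets, durations and condition labels."""

    tr_seconds: float
    n_trs: int
    block_onsets: tuple[float, ...]
    block_duration: float
    blank_duration: float
    initial_blank: float
    condition_per_block: tuple[str, ...]

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)

    @property
    def total_seconds(self) -> float:
        return self.initial_blank + self.n_blocks * (
            self.block_duration + self.blank_duration
        )

    def block_tr_slice(self, i: int) -> slice:
        """TR indices of block ``i`` plus its trailing blank.

        A TR belongs to the segment iff its midpoint lies within
        ``(onset, onset + block + blank]``; with half-TR onsets this
        partitions the run exactly (no TR claimed by two blocks).
        """
        onset = self.block_onsets[i]
        end = onset + self.block_duration + self.blank_duration
        lo = math.floor(onset / self.tr_seconds - 0.5 + 1e-9) + 1
        hi = math.floor(end / self.tr_seconds - 0.5 + 1e-9) + 1
        return slice(max(lo, 0), min(hi, self.n_trs))

    def condition_blocks(self, condition: str) -> list[int]:
        return [i for i, c in enumerate(self.condition_per_block) if c == condition]


@dataclass(frozen=True)
class SFSequence:
    """Probe spatial frequency per frame and per TR for one run."""

    sf_per_tr: np.ndarray = field(repr=False)
    sf_per_frame: np.ndarray = field(repr=False)
    blank_code: float
    sf_levels: np.ndarray = field(repr=False)
    frame_hz: float


def _check_frame_compatible(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    n = value / _FRAME_S
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{name}={value} s is not a multiple of the {_FRAME_S} s frame and "
            "cannot be sampled on the stimulus clock"
        )


def build_run_design(
    n_blocks: int = 6,
    block_s: float = 40.5,
    blank_s: float = 10.0,
    initial_blank_s: float = 10.0,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> RunDesign:
    """Build one run: ``initial_blank_s`` then ``n_blocks`` blocks of
    ``block_s`` seconds, each followed by a ``blank_s`` blank.

    Conditions are interleaved pseudorandomly (seeded), each appearing
    ``n_blocks / len(conditions)`` times.  Defaults reproduce the study
    timeline: 10 s + 6 x (40.5 + 10) s = 313 TRs at TR = 1 s.
    """
    for name, v in [("block_s", block_s), ("blank_s", blank_s),
                    ("initial_blank_s", initial_blank_s)]:
        _check_frame_compatible(name, v)
    if n_blocks > 0 and block_s <= 0:
        raise ValueError("block_s must be positive")
    if n_blocks < 0:
        raise ValueError("n_blocks must be non-negative")
    if n_blocks % max(len(conditions), 1):
        raise ValueError(
            f"{n_blocks} blocks cannot be split evenly over {len(conditions)} conditions"
        )

    total = initial_blank_s + n_blocks * (block_s + blank_s)
    n_trs = int(math.ceil(total / tr_seconds))
    onsets = tuple(
        initial_blank_s + i * (block_s + blank_s) for i in range(n_blocks)
    )
    per = n_blocks // len(conditions) if n_blocks else 0
    labels = np.repeat(conditions, per)
    rng = np.random.default_rng(seed)
    order = tuple(labels[rng.permutation(len(labels))]) if n_blocks else ()
    return RunDesign(
        tr_seconds=tr_seconds,
        n_trs=n_trs,
        block_onsets=onsets,
        block_duration=block_s,
        blank_duration=blank_s,
        initial_blank=initial_blank_s,
        condition_per_block=order,
    )


def build_session_schedule(
    n_runs: int = 9,
    design_template: RunDesign | None = None,
    seed: int = 0,
) -> list[RunDesign]:
    """Replicate a run design across a session with per-run condition orders.

    Sub-seeds are derived by `numpy.random.SeedSequence` spawning so any
    single run is regenerable in isolation.  Defaults give the study's
    nine-run session: 2 blocks/condition/run -> 18 blocks per condition.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    tpl = design_template or build_run_design(seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    runs = []
    for child in children:
        rng = np.random.default_rng(child)
        labels = np.asarray(tpl.condition_per_block)
        order = tuple(np.sort(labels)[rng.permutation(len(labels))])
        runs.append(
            RunDesign(
                tr_seconds=tpl.tr_seconds,
                n_trs=tpl.n_trs,
                block_onsets=tpl.block_onsets,
                block_duration=tpl.block_duration,
                blank_duration=tpl.blank_duration,
                initial_blank=tpl.initial_blank,
                condition_per_block=order,
            )
        )
    return runs


def sf_levels(n_levels: int = 40, sf_min: float = 0.1, sf_max: float = 12.0) -> np.ndarray:
    """The probe center SFs: ``n_levels`` log-spaced values in cpd."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not 0 < sf_min < sf_max:
        raise ValueError("need 0 < sf_min < sf_max")
    return np.logspace(np.log10(sf_min), np.log10(sf_max), n_levels)


def build_probe_sf_sequence(
    design: RunDesign,
    n_levels: int = 40,
    sf_min: float = 0.1,
    sf_max: float = 12.0,
    frame_hz: float = 10.0,
    seed: int = 0,
) -> SFSequence:
    """Assign probe SFs to stimulus frames and down-sample to TRs.

    Within each block the levels appear once each, in a seeded pseudorandom
    permutation, each holding ``floor(frames_per_block / n_levels)`` frames;
    leftover frames extend the final level (40 levels x 1.0 s + 0.5 s in the
    default 40.5 s block).  Blank frames carry the sentinel `BLANK_SF`.  The
    TR track takes the level occupying the majority of each TR's frames,
    ties going to the earlier-onset level.
    """
    levels = sf_levels(n_levels, sf_min, sf_max)
    n_frames = int(round(design.total_seconds * frame_hz))
    frames_per_block = int(round(design.block_duration * frame_hz))
    if design.n_blocks and frames_per_block < n_levels:
        raise ValueError(
            f"block of {frames_per_block} frames cannot present {n_levels} levels"
        )
    dwell = frames_per_block // n_levels if design.n_blocks else 0

    # level index per frame; -1 codes blank
    idx = np.full(n_frames, -1, dtype=int)
    children = np.random.SeedSequence(seed).spawn(max(design.n_blocks, 1))
    for b, onset in enumerate(design.block_onsets):
        rng = np.random.default_rng(children[b])
        perm = rng.permutation(n_levels)
        start = int(round(onset * frame_hz))
        reps = np.full(n_levels, dwell)
        reps[-1] += frames_per_block - dwell * n_levels
        idx[start:start + frames_per_block] = np.repeat(perm, reps)

    sf_per_frame = np.where(idx >= 0, levels[np.clip(idx, 0, None)], BLANK_SF)

    frames_per_tr = int(round(design.tr_seconds * frame_hz))
    sf_per_tr = np.full(design.n_trs, BLANK_SF)
    for t in range(design.n_trs):
        chunk = idx[t * frames_per_tr:(t + 1) * frames_per_tr]
        if chunk.size == 0:
            continue
        # majority level; ties -> earliest first occurrence within the TR
        vals, first, counts = np.unique(chunk, return_index=True, return_counts=True)
        best = np.flatnonzero(counts == counts.max())
        win = vals[best[np.argmin(first[best])]]
        sf_per_tr[t] = levels[win] if win >= 0 else BLANK_SF

    return SFSequence(
        sf_per_tr=sf_per_tr,
        sf_per_frame=sf_per_frame,
        blank_code=BLANK_SF,
        sf_levels=levels,
        frame_hz=frame_hz,
    )
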