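"""Anaesthesia movement scoring from brightfield time-lapse series.

The movement index of a well is, for each pair of consecutive frames, the
mean over pixels of the squared intensity difference — a registration-free
readout of embryo motion. A fully anaesthetized embryo leaves only the
camera-noise floor (twice the per-frame noise variance); a moving embryo
adds the squared contrast along its displaced outline. Plates started at
different developmental stages are aligned by user-supplied stage offsets
before conditions are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .fluor import compare_groups
from .plateio import WellImageSeries

log = logging.getLogger("fishscreen")


@dataclass
class MovementTrace:
    """Per-well movement-index time series.

    ``values`` holds one (time, index) pair per consecutive frame pair,
    timestamped at the later frame; length = frames - 1. The index is the
    mean (not sum) over pixels, so it is independent of image size
    (``index_convention`` records this).
    """

    well: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    index_convention: str = "mean-per-pixel"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"well": self.well, "condition": self.condition,
                             "time_hpf": self.times, "index": self.values})


def squared_difference_index(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Mean over pixels of (frame_b - frame_a)^2.

    Integer frames are computed in exact int64 arithmetic with a single
    final division, so the result is reproducible bit-for-bit against any
    exact per-pixel evaluation; float frames use float64.
    """
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError("frames must share dimensions")
    if np.issubdtype(a.dtype, np.integer) and np.issubdtype(b.dtype, np.integer):
        d = b.astype(np.int64) - a.astype(np.int64)
        return float(int((d * d).sum()) / d.size)
    d = b.astype(np.float64) - a.astype(np.float64)
    return float((d * d).sum() / d.size)


def movement_index(series: WellImageSeries, condition: str = "") -> MovementTrace:
    """Movement index of one brightfield series.

    Requires at least two frames of identical dimensions; multi-z series
    are not meaningful here (the assay acquires a single autofocused
    slice) and are rejected.
    """
    z = series.z_indices
    if len(z) != 1:
        raise ValueError("movement_index expects a single-z brightfield series")
    frames = sorted(series.frames, key=lambda f: f.time_hpf)
    if len(frames) < 2:
        raise ValueError("movement_index needs at least two frames")
    times = np.array([f.time_hpf for f in frames[1:]])
    values = np.array([
        squared_difference_index(frames[i].image, frames[i + 1].image)
        for i in range(len(frames) - 1)
    ])
    return MovementTrace(well=series.well, condition=condition,
                         times=times, values=values)


def movement_table(
    series: Mapping[tuple[str, str], WellImageSeries],
    layout_assignment: Mapping[str, str],
    brightfield_channel: str = "BF",
) -> pd.DataFrame:
    """Movement traces for every well of a plate, as one long table."""
    frames = []
    for (well, ch), s in sorted(series.items()):
        if ch != brightfield_channel:
            continue
        trace = movement_index(s, condition=layout_assignment.get(well, "unknown"))
        frames.append(trace.to_frame())
    if not frames:
        return pd.DataFrame(columns=["well", "condition", "time_hpf", "index"])
    return pd.concat(frames, ignore_index=True)


def stage_align(
    plate_traces: Mapping[str, pd.DataFrame],
    stage_offsets: Mapping[str, float],
) -> pd.DataFrame:
    """Shift each plate's times so a common developmental stage is time 0.

    Time 0 is set by the most advanced plate's starting stage.
    ``stage_offsets`` gives, per plate, the native time in hours at which
    that plate reaches the reference stage: the most advanced plate has
    offset 0, a plate lagging by 2 h has offset +2 and all its times are
    reduced by 2 h. Staging is a manual act, so offsets are user inputs.
    Rows outside the plates' common overlap window are retained but
    flagged ``in_overlap = False``.
    """
    missing = [p for p in plate_traces if p not in stage_offsets]
    if missing:
        raise AlignmentError(f"no stage offset for plate(s): {missing}")
    shifted = []
    for name, df in plate_traces.items():
        out = df.copy()
        if "plate" in out.columns:
            out = out.drop(columns="plate")
        out["time_hpf"] = out["time_hpf"] - float(stage_offsets[name])
        out.insert(0, "plate", name)
        shifted.append(out)
    aligned = pd.concat(shifted, ignore_index=True)
    t_lo = max(df["time_hpf"].min() for df in shifted)
    t_hi = min(df["time_hpf"].max() for df in shifted)
    aligned["in_overlap"] = (aligned["time_hpf"] >= t_lo) & (aligned["time_hpf"] <= t_hi)
    if t_lo > t_hi:
        log.warning("stage_align: plates share no overlapping window after alignment")
    return aligned


def summarize_movement(
    aligned: pd.DataFrame,
    exclude_wells: set[str] | None = None,
) -> pd.DataFrame:
    """Per-condition, per-timepoint mean/sd/n of the movement index.

    ``exclude_wells`` removes negative wells identified by QC. Summaries
    are computed on each plate's own time grid (native sampling).
    """
    df = aligned
    if exclude_wells:
        df = df[~df["well"].isin(exclude_wells)]
    rows = []
    for (condition, t), grp in df.groupby(["condition", "time_hpf"]):
        vals = grp["index"].to_numpy(dtype=float)
        rows.append({"condition": condition, "time_hpf": float(t),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n_wells": int(len(vals))})
    return pd.DataFrame(rows, columns=["condition", "time_hpf", "mean", "sd", "n_wells"])


def score_startle(
    response_counts: Mapping[str, int],
    groups: Mapping[str, str],
    trials: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize startle-response counts and compare groups pairwise.

    Each fish is startled ``trials`` times; ``response_counts`` maps fish
    id to the number of responses, ``groups`` maps fish id to condition.

    Returns
    -------
    (summary, pairwise)
        ``summary``: condition, n_fish, mean, median responses.
        ``pairwise``: condition_a, condition_b, p, stars via the rank-sum
        comparison of :func:`fluor.compare_groups`.
    """
    for fish, count in response_counts.items():
        if not (0 <= count <= trials):
            raise ValueError(f"fish {fish!r}: count {count} outside [0, {trials}]")
        if fish not in groups:
            raise ValueError(f"fish {fish!r} has no group assignment")
    by_group: dict[str, list[int]] = {}
    for fish, count in response_counts.items():
        by_group.setdefault(groups[fish], []).append(count)
    summary = pd.DataFrame(
        [{"condition": g, "n_fish": len(v),
          "mean": float(np.mean(v)), "median": float(np.median(v))}
         for g, v in sorted(by_group.items())],
        columns=["condition", "n_fish", "mean", "median"])
    names = sorted(by_group)
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p, stars = compare_groups(by_group[a], by_group[b])
            pair_rows.append({"condition_a": a, "condition_b": b, "p": p, "stars": stars})
    pairwise = pd.DataFrame(pair_rows, columns=["condition_a", "condition_b", "p", "stars"])
    return summary, pairwise
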