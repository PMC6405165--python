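"""Ratiometric fluorescence traces: normalization, QC, fusion, ranking,
cross-species comparison and group tests.

The screening readout is the per-well ratio of a test fluorophore to a
co-injected reference fluorophore. Dividing by the reference value at the
normalization timepoint (nearest acquired frame to 10 hpf) cancels the
injection-volume differences between wells. Plates are fused onto one
axis by rescaling with the internal-control condition, conditions are
ranked by normalized intensity, and cross-species comparisons rescale
each colour class to an external reference value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCParams
from .errors import EmptyMaskError, FusionError, NormalizationError
from .layout import PlateLayout
from .plateio import WellImageSeries
from .segment import aggregate_z, dual_channel_mask, measure_masked

log = logging.getLogger("fishscreen")

#: Significance-star thresholds, inclusive upper bounds applied in order.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

MEASUREMENT_COLUMNS = ["well", "channel", "time_hpf", "z",
                       "mean", "median", "sd", "area", "bg_mean"]


@dataclass
class IntensityTrace:
    """Per-well intensity time series, raw or reference-normalized."""

    well: str
    condition: str
    channel_role: str  # "test" or "reference"
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    normalization_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def value_near(self, t: float) -> float:
        """Value at the acquired timepoint nearest ``t`` (no interpolation)."""
        return float(self.values[int(np.argmin(np.abs(self.times - t)))])


def nearest_time(times: np.ndarray, t: float) -> float:
    times = np.asarray(times, dtype=float)
    return float(times[int(np.argmin(np.abs(times - t)))])


def quantify_plate(
    series: Mapping[tuple[str, str], WellImageSeries],
    reference_channel: str,
) -> pd.DataFrame:
    """Segment and measure every frame of a dual-channel acquisition.

    For each well/timepoint/z-slice the mask is the intersection of both
    channels' Otsu foregrounds; both channels are measured with that same
    mask. Frames with an empty mask yield no measurement row (QC sees the
    missing checkpoint). Returns the per-slice ``measurements`` table.
    """
    rows = []
    wells = sorted({w for (w, _) in series})
    for well in wells:
        channels = sorted(ch for (w, ch) in series if w == well)
        if reference_channel not in channels:
            log.warning("quantify_plate: well %s lacks reference channel, skipped", well)
            continue
        ref = series[(well, reference_channel)]
        for t in ref.times:
            for f_ref in ref.frames_at(t):
                for ch in channels:
                    if ch == reference_channel:
                        continue
                    f_test = series[(well, ch)].frame(t, f_ref.z)
                    mask = dual_channel_mask(f_test.image, f_ref.image)
                    if not mask.any():
                        log.debug("empty mask: %s t=%.3f z=%d", well, t, f_ref.z)
                        continue
                    for chan, img in ((ch, f_test.image), (reference_channel, f_ref.image)):
                        st = measure_masked(img, mask)
                        rows.append({"well": well, "channel": chan,
                                     "time_hpf": float(t), "z": int(f_ref.z),
                                     "mean": st.mean, "median": st.median,
                                     "sd": st.sd, "area": st.area,
                                     "bg_mean": st.bg_mean})
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def aggregate_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-slice measurements to one row per well/channel/timepoint
    (area-weighted pooling across z, see :func:`segment.aggregate_z`)."""
    from .segment import RegionStats

    rows = []
    for (well, ch, t), grp in measurements.groupby(["well", "channel", "time_hpf"]):
        stats_list = [RegionStats(mean=r["mean"], median=r["median"], sd=r["sd"],
                                  area=int(r["area"]), bg_mean=r["bg_mean"])
                      for _, r in grp.iterrows()]
        agg = aggregate_z(stats_list)
        rows.append({"well": well, "channel": ch, "time_hpf": t, "z": -1,
                     "mean": agg.mean, "median": agg.median, "sd": agg.sd,
                     "area": agg.area, "bg_mean": agg.bg_mean})
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def normalize_trace(
    test: IntensityTrace,
    reference: IntensityTrace,
    t_norm: float,
) -> IntensityTrace:
    """Divide a test trace by the reference value nearest ``t_norm``.

    Raises
    ------
    NormalizationError
        If the traces come from different wells or the reference value at
        the normalization timepoint is missing or non-positive (the well
        is a negative well and must be excluded).
    """
    if test.well != reference.well:
        raise NormalizationError(
            f"traces from different wells: {test.well} vs {reference.well}")
    ref_val = reference.value_near(t_norm)
    if not np.isfinite(ref_val) or ref_val <= 0:
        raise NormalizationError(
            f"well {test.well}: reference value {ref_val!r} at {t_norm} hpf")
    return IntensityTrace(
        well=test.well,
        condition=test.condition,
        channel_role=test.channel_role,
        times=test.times.copy(),
        values=test.values / ref_val,
        normalized=True,
        normalization_time=nearest_time(reference.times, t_norm),
    )


def qc_filter(
    aggregated: pd.DataFrame,
    params: QCParams,
    channel: str | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Drop negative wells (dead or non-developing embryos).

    A well is kept iff at every checkpoint timepoint (fractions of the
    series, default final and midpoint) the mask area reaches
    ``params.min_area`` and the masked mean reaches
    ``params.min_signal_ratio`` times the background mean. Filtering is
    total: every well is either kept or dropped with a reason.

    Parameters
    ----------
    aggregated : DataFrame
        Per well/channel/timepoint rows (``aggregate_measurements``).
    channel : str, optional
        Channel whose signal is checked (default: the reference channel's
        rows if unambiguous, else all channels must pass).

    Returns
    -------
    (kept, dropped)
        ``kept`` is a set of well names; ``dropped`` is a DataFrame with
        columns ``well`` and ``reason``.
    """
    df = aggregated if channel is None else aggregated[aggregated["channel"] == channel]
    kept: set[str] = set()
    dropped_rows = []
    for well, grp in df.groupby("well"):
        times = np.sort(grp["time_hpf"].unique())
        n = len(times)
        reasons = []
        for frac in params.checkpoints:
            idx = int(round(frac * (n - 1)))
            t = times[idx]
            row = grp[grp["time_hpf"] == t]
            if row.empty:
                reasons.append(f"no measurement at checkpoint {frac:g}")
                continue
            row = row.iloc[0]
            if row["area"] < params.min_area:
                reasons.append(f"area {int(row['area'])} < {params.min_area} at {t:g} hpf")
            bg = row["bg_mean"]
            if np.isfinite(bg) and row["mean"] < params.min_signal_ratio * bg:
                reasons.append(
                    f"no signal at checkpoint {frac:g} "
                    f"(mean {row['mean']:.1f} < {params.min_signal_ratio:g} x bg {bg:.1f})")
        if reasons:
            dropped_rows.append({"well": well, "reason": "; ".join(reasons)})
        else:
            kept.add(well)
    return kept, pd.DataFrame(dropped_rows, columns=["well", "reason"])


def build_traces(
    aggregated: pd.DataFrame,
    plate_layout: PlateLayout,
    reference_channel: str,
    t_norm: float,
    wells: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-well normalized traces from aggregated measurements.

    Returns the long-format ``traces`` table (well, condition, channel,
    channel_role, time_hpf, value) and a table of wells excluded by
    normalization failures.
    """
    rows = []
    failures = []
    for well, grp in aggregated.groupby("well"):
        if wells is not None and well not in wells:
            continue
        condition = plate_layout.assignment.get(well, "unknown")
        ref_grp = grp[grp["channel"] == reference_channel].sort_values("time_hpf")
        if ref_grp.empty:
            failures.append({"well": well, "reason": "no reference-channel data"})
            continue
        reference = IntensityTrace(
            well=well, condition=condition, channel_role="reference",
            times=ref_grp["time_hpf"].to_numpy(), values=ref_grp["mean"].to_numpy())
        for ch, ch_grp in grp.groupby("channel"):
            role = "reference" if ch == reference_channel else "test"
            ch_grp = ch_grp.sort_values("time_hpf")
            trace = IntensityTrace(
                well=well, condition=condition, channel_role=role,
                times=ch_grp["time_hpf"].to_numpy(), values=ch_grp["mean"].to_numpy())
            try:
                norm = normalize_trace(trace, reference, t_norm)
            except NormalizationError as exc:
                failures.append({"well": well, "reason": str(exc)})
                break
            for t, v in zip(norm.times, norm.values):
                rows.append({"well": well, "condition": condition, "channel": ch,
                             "channel_role": role, "time_hpf": t, "value": v})
    return (pd.DataFrame(rows, columns=["well", "condition", "channel",
                                        "channel_role", "time_hpf", "value"]),
            pd.DataFrame(failures, columns=["well", "reason"]))


def fuse_plates(
    plates: Mapping[str, pd.DataFrame],
    control_condition: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Rescale plates onto one axis via the internal-control condition.

    The first plate (mapping order) is the reference. Every other plate's
    values are multiplied by ``s_p = mean(reference control) / mean(plate
    control)``, both means taken over the plates' common time window, so
    the control curves coincide after fusion. Trace tables need columns
    ``condition``, ``time_hpf`` and ``value``.

    Returns the fused long table (with a ``plate`` column) and the
    per-plate factors. Fusing an already-fused result gives factors of 1.
    """
    if not plates:
        raise FusionError("no plates to fuse")
    names = list(plates)
    for name, df in plates.items():
        if not (df["condition"] == control_condition).any():
            raise FusionError(f"plate {name!r} lacks control condition {control_condition!r}")
    t_lo = max(df["time_hpf"].min() for df in plates.values())
    t_hi = min(df["time_hpf"].max() for df in plates.values())
    if t_lo > t_hi:
        raise FusionError("plates share no overlapping time window")

    def control_mean(df: pd.DataFrame) -> float:
        sel = df[(df["condition"] == control_condition)
                 & (df["time_hpf"] >= t_lo) & (df["time_hpf"] <= t_hi)]
        if "channel_role" in df.columns and (sel["channel_role"] == "test").any():
            sel = sel[sel["channel_role"] == "test"]
        if sel.empty:
            raise FusionError(f"no control values of {control_condition!r} in the common window")
        return float(sel["value"].mean())

    ref_mean = control_mean(plates[names[0]])
    factors: dict[str, float] = {}
    fused = []
    for name in names:
        df = plates[name].copy()
        if "plate" in df.columns:
            df = df.drop(columns="plate")
        s = ref_mean / control_mean(df)
        factors[name] = s
        df["value"] = df["value"] * s
        df.insert(0, "plate", name)
        fused.append(df)
    return pd.concat(fused, ignore_index=True), factors


def rank_conditions(traces: pd.DataFrame, t: float) -> pd.DataFrame:
    """Order conditions by mean normalized intensity at the timepoint
    nearest ``t`` (descending; ties broken by condition label).

    Only test-channel values contribute when a ``channel_role`` column is
    present. Returns columns condition, mean, sd, n_wells.
    """
    df = traces
    if "channel_role" in df.columns and (df["channel_role"] == "test").any():
        df = df[df["channel_role"] == "test"]
    rows = []
    for condition, grp in df.groupby("condition"):
        t_star = nearest_time(grp["time_hpf"].unique(), t)
        at_t = grp[grp["time_hpf"] == t_star]
        vals = at_t.groupby("well")["value"].mean()
        rows.append({"condition": condition, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n_wells": int(len(vals))})
    out = pd.DataFrame(rows, columns=["condition", "mean", "sd", "n_wells"])
    return (out.sort_values(["mean", "condition"], ascending=[False, True])
               .reset_index(drop=True))


def window_means(
    traces: pd.DataFrame,
    t_lo: float = 23.0,
    t_hi: float = 30.0,
) -> dict[str, float]:
    """Per-condition mean of all values with ``t_lo <= t <= t_hi`` (hpf)."""
    df = traces
    if "channel_role" in df.columns and (df["channel_role"] == "test").any():
        df = df[df["channel_role"] == "test"]
    sel = df[(df["time_hpf"] >= t_lo) & (df["time_hpf"] <= t_hi)]
    return {c: float(g["value"].mean()) for c, g in sel.groupby("condition")}


def cross_species_table(
    internal_means: Mapping[str, float],
    reference_values: Mapping[str, float],
    colour_class: Mapping[str, str],
    class_normalizers: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Rescale in-vivo window means onto external per-class reference values.

    Within each colour class (green / red / yellow) every condition's
    internal mean is multiplied by the factor that maps the class
    normalizer's internal mean exactly onto its external reference value
    (e.g. the yellow normalizer is pinned to 1.2). Classes whose
    normalizer is missing or non-positive are excluded with an error
    record.

    Returns
    -------
    (table, errors)
        Table columns: condition, colour_class, normalized_internal,
        reference. ``errors`` lists human-readable per-class problems.
    """
    errors: list[str] = []
    scale: dict[str, float] = {}
    for cls, normalizer in class_normalizers.items():
        internal = internal_means.get(normalizer)
        external = reference_values.get(normalizer)
        if internal is None or not np.isfinite(internal) or internal <= 0:
            errors.append(f"class {cls!r}: normalizer {normalizer!r} missing or non-positive")
            continue
        if external is None:
            errors.append(f"class {cls!r}: normalizer {normalizer!r} has no reference value")
            continue
        scale[cls] = external / internal
    rows = []
    for condition, internal in internal_means.items():
        cls = colour_class.get(condition)
        if cls not in scale:
            continue
        rows.append({"condition": condition, "colour_class": cls,
                     "normalized_internal": internal * scale[cls],
                     "reference": reference_values.get(condition, float("nan"))})
    table = pd.DataFrame(rows, columns=["condition", "colour_class",
                                        "normalized_internal", "reference"])
    return table.sort_values("condition").reset_index(drop=True), errors


def star_label(p: float) -> str:
    """Significance stars from a p value (inclusive upper bounds)."""
    for bound, stars in STAR_THRESHOLDS:
        if p <= bound:
            return stars
    return "ns"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
) -> tuple[float, str]:
    """Two-sided rank-sum comparison of two samples with a star label."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0, "ns"  # identical constant samples: no evidence of difference
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, star_label(p)
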