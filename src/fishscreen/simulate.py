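"""Ground-truthed synthetic plate acquisitions.

Emulates the two screening assay designs on a 96-well plate so that every
downstream stage (segmentation, normalization, QC, fusion, ranking,
movement scoring) can be verified against known truth:

* fluorophore assay — two fluorescence channels, several z-slices, long
  time-lapse; per-well expression follows a two-timescale rise-and-decay
  kinetic (chromophore maturation followed by slow loss of signal after an
  mRNA bolus), scaled by a per-well injection-volume factor shared across
  channels (co-injected mRNAs scale together, the premise of ratiometric
  normalization);
* anaesthesia assay — single-slice brightfield time-lapse in which the
  embryo (rendered darker than background) performs a clamped 2-D random
  walk whose per-frame step is the condition's movement amplitude.

Dead / non-developing wells show background only in fluorescence channels
and a motionless embryo in brightfield. Images are 16-bit grayscale TIFFs;
the generator records every drawn quantity in a :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .layout import EMPTY, PlateLayout
from .plateio import DEFAULT_PATTERN, Frame, WellImageSeries, format_name

#: Brightfield rendering levels (counts): background bright, embryo dark.
BRIGHTFIELD_BACKGROUND = 20000.0
BRIGHTFIELD_EMBRYO = 8000.0

#: Curvature of the parabolic z attenuation profile (shared across
#: channels, so channel ratios are z-independent by construction).
Z_PROFILE_DEPTH = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition parameters for one simulated plate.

    Times are hours post fertilization (hpf); ``t_step`` is in minutes,
    matching plate-imager conventions (20-33 min intervals). Pixel noise
    is Gaussian with standard deviation ``noise_sd + noise_fraction *
    clean_intensity``: a constant read-noise term plus a shot-like term
    proportional to the local noise-free intensity. ``injection_volume_cv``
    is the coefficient of variation of the log-normal per-well
    injection-volume factor (mean 1).
    """

    plate_rows: int = 8
    plate_cols: int = 12
    image_size: int = 64
    t_start: float = 0.0
    t_end: float = 40.0
    t_step: float = 20.0
    z_slices: int = 1
    channels: tuple[str, ...] = ("GFP", "mCherry")
    background_level: float = 100.0
    noise_sd: float = 10.0
    noise_fraction: float = 0.0
    embryo_radius: int = 14
    injection_volume_cv: float = 0.3
    dead_well_fraction: float = 0.0
    seed: int = 0
    brightfield_channels: tuple[str, ...] = ("BF",)

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ConfigError("t_end must exceed t_start")
        if self.t_step <= 0:
            raise ConfigError("t_step must be positive")
        if self.image_size <= 4 * self.embryo_radius:
            raise ConfigError("image_size must exceed 4 x embryo_radius")
        if not (0.0 <= self.dead_well_fraction <= 1.0):
            raise ConfigError("dead_well_fraction must lie in [0, 1]")
        if self.z_slices < 1 or self.plate_rows < 1 or self.plate_cols < 1:
            raise ConfigError("counts must be positive")
        if self.injection_volume_cv < 0 or self.noise_sd < 0 or self.background_level < 0:
            raise ConfigError("levels must be non-negative")
        if self.noise_fraction < 0:
            raise ConfigError("noise_fraction must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Acquisition timepoints in hpf."""
        n = int(np.floor((self.t_end - self.t_start) * 60.0 / self.t_step)) + 1
        return self.t_start + np.arange(n) * self.t_step / 60.0


@dataclass(frozen=True)
class ConditionModel:
    """Per-condition expression kinetics and behaviour.

    ``brightness`` maps channel name to the asymptotic signal amplitude in
    counts; channels absent from the mapping express nothing. The kinetic
    is ``I(t) = v * b * (1 - exp(-t / maturation_time)) * exp(-t / decay_time)``
    with times in hpf. ``movement_amplitude`` is the embryo displacement in
    pixels per frame (0 for a fully anaesthetized condition).
    """

    name: str
    brightness: Mapping[str, float] = field(default_factory=dict)
    maturation_time: float = 3.0
    decay_time: float = 30.0
    movement_amplitude: float = 0.0
    is_reference_channel_only: bool = False

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.brightness.values()):
            raise ConfigError(f"{self.name}: brightness must be non-negative")
        if self.maturation_time <= 0 or self.decay_time <= 0:
            raise ConfigError(f"{self.name}: kinetic times must be positive")
        if self.movement_amplitude < 0:
            raise ConfigError(f"{self.name}: movement_amplitude must be non-negative")

    def kinetic(self, t: np.ndarray | float) -> np.ndarray | float:
        """Dimensionless rise-and-decay factor at time t (hpf)."""
        t = np.asarray(t, dtype=float)
        return (1.0 - np.exp(-t / self.maturation_time)) * np.exp(-t / self.decay_time)


@dataclass
class WellTruth:
    """Everything drawn for one simulated well."""

    well: str
    condition: str
    injection_volume_factor: float
    brightness: dict[str, float]
    true_brightness_ratio: float
    is_dead: bool
    centroid_track: np.ndarray  # (n_timepoints, 2) of (x, y)
    clamped: bool


@dataclass
class GroundTruth:
    """Per-well truth records for a simulated plate."""

    wells: dict[str, WellTruth] = field(default_factory=dict)

    def dead_wells(self) -> set[str]:
        return {w for w, t in self.wells.items() if t.is_dead}

    def to_frame(self) -> pd.DataFrame:
        records = []
        for t in self.wells.values():
            rec = {
                "well": t.well,
                "condition": t.condition,
                "injection_volume_factor": t.injection_volume_factor,
                "true_brightness_ratio": t.true_brightness_ratio,
                "is_dead": t.is_dead,
                "clamped": t.clamped,
            }
            for ch, b in t.brightness.items():
                rec[f"brightness_{ch}"] = b
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def track_frame(self) -> pd.DataFrame:
        records = []
        for t in self.wells.values():
            for i, (x, y) in enumerate(t.centroid_track):
                records.append({"well": t.well, "t_index": i, "x": x, "y": y})
        return pd.DataFrame.from_records(records)


def _disk_mask(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _z_factor(z: int, n_z: int) -> float:
    """Parabolic focus profile across the z-stack, 1 at the central slice."""
    if n_z == 1:
        return 1.0
    half = (n_z - 1) / 2.0
    return 1.0 - Z_PROFILE_DEPTH * ((z - half) / half) ** 2


def simulate_plate(
    config: SimulationConfig,
    plate_layout: PlateLayout,
    models: Mapping[str, ConditionModel],
    reference_channel: str | None = None,
) -> tuple[dict[tuple[str, str], WellImageSeries], GroundTruth]:
    """Simulate one plate acquisition.

    Parameters
    ----------
    config : SimulationConfig
        Acquisition geometry, kinetic time grid, noise and cohort settings.
    plate_layout : PlateLayout
        Well-to-condition assignment; empty wells are not imaged.
    models : mapping
        ``condition label -> ConditionModel``; every condition occurring in
        the layout must have a model.
    reference_channel : str, optional
        Channel used as the denominator of ``true_brightness_ratio``
        (defaults to the last configured channel).

    Returns
    -------
    (series, truth)
        ``series`` maps ``(well, channel)`` to a :class:`WellImageSeries`;
        ``truth`` records every drawn quantity. Identical inputs (including
        the seed) give bit-identical outputs.
    """
    missing = {c for c in plate_layout.counts() if c not in models}
    if missing:
        raise ConfigError(f"layout conditions without a model: {sorted(missing)}")
    if reference_channel is None:
        reference_channel = config.channels[-1]

    times = config.times
    n_t = len(times)
    size = config.image_size
    r = config.embryo_radius
    lo, hi = r + 1.0, size - r - 2.0
    sigma_ln = float(np.sqrt(np.log1p(config.injection_volume_cv**2)))

    rng = np.random.default_rng(config.seed)
    series: dict[tuple[str, str], WellImageSeries] = {}
    truth = GroundTruth()

    for well in plate_layout.occupied_wells:
        condition = plate_layout.condition_of(well)
        model = models[condition]
        is_dead = bool(rng.random() < config.dead_well_fraction)
        # mean-1 log-normal injection volume, shared across channels
        v = float(rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln))

        # bounded random walk of the embryo centroid (fixed step length,
        # uniform heading); dead embryos do not move
        track = np.empty((n_t, 2))
        track[0] = (size / 2.0, size / 2.0)
        angles = rng.uniform(0.0, 2.0 * np.pi, size=max(n_t - 1, 0))
        amp = 0.0 if is_dead else model.movement_amplitude
        clamped = False
        for i in range(1, n_t):
            step = amp * np.array([np.cos(angles[i - 1]), np.sin(angles[i - 1])])
            nxt = track[i - 1] + step
            clipped = np.clip(nxt, lo, hi)
            if not np.array_equal(clipped, nxt):
                clamped = True
            track[i] = clipped

        brightness = {ch: float(model.brightness.get(ch, 0.0)) for ch in config.channels}
        if model.is_reference_channel_only:
            brightness = {ch: (b if ch == reference_channel else 0.0)
                          for ch, b in brightness.items()}
        fluor_channels = [ch for ch in config.channels
                         if ch not in config.brightfield_channels]
        test_channels = [ch for ch in fluor_channels if ch != reference_channel]
        if test_channels and brightness.get(reference_channel, 0.0) > 0:
            ratio = brightness[test_channels[0]] / brightness[reference_channel]
        else:
            ratio = float("nan")

        kin = model.kinetic(times)
        for i, t in enumerate(times):
            cx, cy = track[i]
            disk = _disk_mask(size, cx, cy, r)
            for ch in config.channels:
                for z in range(config.z_slices):
                    if ch in config.brightfield_channels:
                        img = np.full((size, size), BRIGHTFIELD_BACKGROUND)
                        img[disk] = BRIGHTFIELD_EMBRYO
                    else:
                        img = np.full((size, size), config.background_level)
                        if not is_dead:
                            signal = v * brightness[ch] * kin[i] * _z_factor(z, config.z_slices)
                            img[disk] += signal
                    sigma = config.noise_sd + config.noise_fraction * img
                    img = img + sigma * rng.standard_normal((size, size))
                    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
                    s = series.setdefault(
                        (well, ch),
                        WellImageSeries(well=well, channel=ch, frames=[], pixel_depth=16),
                    )
                    s.frames.append(Frame(time_hpf=float(t), z=z, image=img))

        truth.wells[well] = WellTruth(
            well=well,
            condition=condition,
            injection_volume_factor=v,
            brightness=brightness,
            true_brightness_ratio=ratio,
            is_dead=is_dead,
            centroid_track=track,
            clamped=clamped,
        )

    for s in series.values():
        s.frames.sort(key=lambda f: (f.time_hpf, f.z))
    return series, truth


def write_plate(
    series: Mapping[tuple[str, str], WellImageSeries],
    truth: GroundTruth,
    config: SimulationConfig,
    directory,
    naming_pattern: str = DEFAULT_PATTERN,
) -> None:
    """Write a simulated plate to disk: TIFFs, ground_truth.csv,
    centroids.csv and acquisition.yaml echoing the configuration."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    times = list(config.times)
    for (well, ch), s in series.items():
        for f in s.frames:
            t_idx = times.index(f.time_hpf)
            name = format_name(naming_pattern, well, t_idx, ch, f.z)
            tifffile.imwrite(directory / name, f.image)
    truth.to_frame().to_csv(directory / "ground_truth.csv", index=False)
    truth.track_frame().to_csv(directory / "centroids.csv", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    cfg["naming_pattern"] = naming_pattern
    with open(directory / "acquisition.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
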