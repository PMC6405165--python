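"""Image-stack and table I/O for plate acquisitions.

One grayscale TIFF per well/channel/z/timepoint, named by a configurable
template (default ``{well}_T{t}_C{channel}_Z{z}.tif``). Frame times are
reconstructed from acquisition indices (``time_origin + index * step``)
rather than file timestamps, so a re-run over the same files is
reproducible to the bit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile

from .errors import AmbiguityError, ConfigError

log = logging.getLogger("fishscreen")

DEFAULT_PATTERN = "{well}_T{t}_C{channel}_Z{z}.tif"

_FIELD_REGEX = {
    "well": r"(?P<well>[A-Za-z]+\d+)",
    "t": r"(?P<t>\d+)",
    "channel": r"(?P<channel>[A-Za-z0-9\-]+)",
    "z": r"(?P<z>\d+)",
}


@dataclass
class Frame:
    """One acquired image: time in hours post fertilization, z index, pixels."""

    time_hpf: float
    z: int
    image: np.ndarray


@dataclass
class WellImageSeries:
    """Ordered image frames for one well and channel.

    Frames are sorted by (time, z); all frames share dimensions and
    intensities are non-negative.
    """

    well: str
    channel: str
    frames: list[Frame] = field(default_factory=list)
    pixel_depth: int = 16

    def __post_init__(self) -> None:
        self.frames.sort(key=lambda f: (f.time_hpf, f.z))

    @property
    def times(self) -> np.ndarray:
        """Unique frame times, ascending."""
        return np.unique([f.time_hpf for f in self.frames])

    @property
    def z_indices(self) -> np.ndarray:
        return np.unique([f.z for f in self.frames])

    def frames_at(self, time_hpf: float) -> list[Frame]:
        """All z-slices acquired at one timepoint, ordered by z."""
        return [f for f in self.frames if f.time_hpf == time_hpf]

    def frame(self, time_hpf: float, z: int) -> Frame:
        for f in self.frames:
            if f.time_hpf == time_hpf and f.z == z:
                return f
        raise KeyError((self.well, self.channel, time_hpf, z))

    def validate(self) -> None:
        shapes = {f.image.shape for f in self.frames}
        if len(shapes) > 1:
            raise ConfigError(f"series {self.well}/{self.channel}: mixed frame shapes {shapes}")
        for f in self.frames:
            if np.any(np.asarray(f.image) < 0):
                raise ConfigError(f"series {self.well}/{self.channel}: negative intensities")
        for z in self.z_indices:
            t = [f.time_hpf for f in self.frames if f.z == z]
            if np.any(np.diff(t) <= 0):
                raise ConfigError(f"series {self.well}/{self.channel}: times not strictly increasing")


def pattern_to_regex(naming_pattern: str) -> re.Pattern:
    """Compile a file-name template into a regex with named groups.

    Placeholders ``{well}``, ``{t}``, ``{channel}``, ``{z}`` are recognised;
    printf-style paddings such as ``{t:03d}`` are accepted and ignored.
    """
    out = []
    pos = 0
    for m in re.finditer(r"\{(well|t|channel|z)(?::[^}]*)?\}", naming_pattern):
        out.append(re.escape(naming_pattern[pos:m.start()]))
        out.append(_FIELD_REGEX[m.group(1)])
        pos = m.end()
    out.append(re.escape(naming_pattern[pos:]))
    body = "".join(out)
    for name in ("well", "t", "channel", "z"):
        if f"(?P<{name}>" not in body:
            raise ConfigError(f"naming pattern lacks a {{{name}}} placeholder")
    return re.compile("^" + body + "$")


def format_name(naming_pattern: str, well: str, t: int, channel: str, z: int) -> str:
    return naming_pattern.format(well=well, t=t, channel=channel, z=z)


def discover_series(
    directory,
    naming_pattern: str = DEFAULT_PATTERN,
    time_origin: float = 0.0,
    time_step: float = 20.0,
) -> dict[tuple[str, str], WellImageSeries]:
    """Scan a directory of TIFFs into per-(well, channel) image series.

    Parameters
    ----------
    directory : path
        Directory holding the acquisition.
    naming_pattern : str
        Template with ``{well}/{t}/{channel}/{z}`` placeholders.
    time_origin : float
        Time of acquisition index 0, in hours post fertilization.
    time_step : float
        Acquisition interval in minutes.

    Returns
    -------
    dict
        ``(well, channel) -> WellImageSeries``. Unparseable file names are
        skipped with a logged count; duplicate coordinates raise
        :class:`AmbiguityError`.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigError(f"not a directory: {directory}")
    regex = pattern_to_regex(naming_pattern)
    series: dict[tuple[str, str], WellImageSeries] = {}
    seen: set[tuple[str, str, int, int]] = set()
    skipped = 0
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        m = regex.match(path.name)
        if m is None:
            skipped += 1
            continue
        well, channel = m.group("well"), m.group("channel")
        t_idx, z_idx = int(m.group("t")), int(m.group("z"))
        key = (well, channel, t_idx, z_idx)
        if key in seen:
            raise AmbiguityError(f"duplicate frame coordinates {key} ({path.name})")
        seen.add(key)
        image = tifffile.imread(path)
        s = series.setdefault(
            (well, channel),
            WellImageSeries(well=well, channel=channel, frames=[],
                            pixel_depth=8 * image.dtype.itemsize),
        )
        s.frames.append(Frame(time_hpf=time_origin + t_idx * time_step / 60.0,
                              z=z_idx, image=image))
    for s in series.values():
        s.frames.sort(key=lambda f: (f.time_hpf, f.z))
    if skipped:
        log.warning("discover_series: skipped %d files not matching %r", skipped, naming_pattern)
    if not series:
        log.warning("discover_series: no matching files in %s", directory)
    return series


def write_series(
    series: Iterable[WellImageSeries],
    directory,
    naming_pattern: str = DEFAULT_PATTERN,
    time_origin: float = 0.0,
    time_step: float = 20.0,
) -> int:
    """Write image series as one TIFF per frame; returns the file count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = 0
    for s in series:
        times = list(s.times)
        for f in s.frames:
            t_idx = int(round((f.time_hpf - time_origin) * 60.0 / time_step))
            if t_idx < 0 or abs(time_origin + t_idx * time_step / 60.0 - f.time_hpf) > 1e-6:
                t_idx = times.index(f.time_hpf)
            name = format_name(naming_pattern, s.well, t_idx, s.channel, f.z)
            tifffile.imwrite(directory / name, np.asarray(f.image))
            n += 1
    return n
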