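"""Analysis configuration: naming convention, time base, channel roles, QC.

Loaded from / saved to YAML so that a whole analysis is reproducible from
the acquisition directory plus one config file.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .plateio import DEFAULT_PATTERN


@dataclass(frozen=True)
class QCParams:
    """Well quality-control parameters.

    A well is kept iff, at the checkpoint timepoints (fractions of the
    series; default the final timepoint and the midpoint), the embryo mask
    has at least ``min_area`` pixels and the masked mean exceeds
    ``min_signal_ratio`` times the background (outside-mask) mean.
    """

    min_area: int = 50
    min_signal_ratio: float = 2.0
    checkpoints: tuple[float, ...] = (1.0, 0.5)

    def __post_init__(self) -> None:
        if self.min_signal_ratio <= 1:
            raise ConfigError("min_signal_ratio must exceed 1")
        if any(not (0 < c <= 1) for c in self.checkpoints):
            raise ConfigError("checkpoints must lie in (0, 1]")


@dataclass
class AnalysisConfig:
    """End-to-end settings for one plate analysis."""

    naming_pattern: str = DEFAULT_PATTERN
    time_origin_hpf: float = 0.0
    time_step_min: float = 20.0
    reference_channel: str = "mCherry"
    test_channels: tuple[str, ...] = ("GFP",)
    brightfield_channel: str = "BF"
    normalization_time_hpf: float = 10.0
    qc: QCParams = field(default_factory=QCParams)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["qc"] = asdict(self.qc)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        qc = data.pop("qc", {})
        if isinstance(qc.get("checkpoints"), list):
            qc["checkpoints"] = tuple(qc["checkpoints"])
        if isinstance(data.get("test_channels"), list):
            data["test_channels"] = tuple(data["test_channels"])
        return cls(qc=QCParams(**qc), **data)


def setup_logging(logfile=None, level=logging.INFO) -> None:
    """Route pipeline logs to stderr and optionally to a file."""
    logger = logging.getLogger("fishscreen")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
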