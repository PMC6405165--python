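"""Exception hierarchy for the screening pipeline."""


class FishscreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(FishscreenError):
    """Invalid simulation or analysis configuration."""


class CapacityError(FishscreenError):
    """Requested replicates exceed the plate capacity."""


class AmbiguityError(FishscreenError):
    """Two files resolve to the same (well, channel, z, timepoint)."""


class DegenerateImageError(FishscreenError):
    """Image histogram has a single class; no threshold exists."""


class EmptyMaskError(FishscreenError):
    """Measurement requested on an empty mask."""


class NormalizationError(FishscreenError):
    """Reference value missing or non-positive at the normalization timepoint."""


class FusionError(FishscreenError):
    """A plate lacks the internal-control condition needed for fusion."""


class AlignmentError(FishscreenError):
    """A plate lacks the stage offset needed for alignment."""


class TableError(FishscreenError):
    """Malformed codon-usage table."""


class SequenceError(FishscreenError):
    """Coding sequence not analysable (length, alphabet, internal stops)."""
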