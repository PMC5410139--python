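"""Exception hierarchy shared across the pipeline."""


class FukomysError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FukomysError):
    """Unparseable or empty input file."""


class AlignmentError(FukomysError):
    """Sequences violate alignment invariants (ragged rows, bad characters)."""


class UndefinedDistanceError(FukomysError):
    """A pairwise distance is undefined (no comparable sites)."""


class SaturationError(UndefinedDistanceError):
    """Distance correction not estimable (log/power argument non-positive)."""


class TreeError(FukomysError):
    """Tree structure or tree/alignment label mismatch."""


class ConfigError(FukomysError):
    """Invalid model or run configuration."""


class ImpossibleDataError(FukomysError):
    """Constraints assign zero probability to the observed data."""


class DegenerateShapeError(FukomysError):
    """Landmark configuration unusable (coincident or collinear landmarks)."""


class StatsError(FukomysError):
    """Statistical routine cannot be computed on the given selection."""
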