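"""Exception hierarchy for hydrocouple.

All package errors derive from :class:`HydrocoupleError` so callers can catch
pipeline failures with a single ``except`` clause while still distinguishing
format problems from configuration or numerical issues.
"""


class HydrocoupleError(Exception):
    """Base class for all hydrocouple errors."""


class FormatMismatchError(HydrocoupleError):
    """Topology and trajectory disagree (atom counts, malformed records)."""


class UnsupportedBoxError(HydrocoupleError):
    """The simulation box is not orthorhombic."""


class EmptyTrajectoryError(HydrocoupleError):
    """A trajectory or selection contains no frames / no data."""


class ConfigurationError(HydrocoupleError):
    """An analysis parameter or selection is invalid for the given system."""


class DegenerateSeriesError(HydrocoupleError):
    """A time series has zero variance and no autocorrelation is defined."""


class InsufficientNeighborsError(HydrocoupleError):
    """Fewer neighbors exist than an order parameter requires."""


class ClassificationError(HydrocoupleError):
    """A residue name or sigma table cannot be classified."""


class UndefinedCorrelationError(HydrocoupleError):
    """Too few paired observations (or zero rank variance) for a correlation."""


class GenerationError(HydrocoupleError):
    """A synthetic-data generator could not satisfy its constraints."""
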