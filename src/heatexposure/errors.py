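"""Exception hierarchy for the heat-exposure pipeline.

Every rejection names the offending record or parameter; readers and
operations never silently coerce invalid input.
"""


class HeatExposureError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(HeatExposureError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(HeatExposureError, ValueError):
    """A file or in-memory structure does not conform to the declared schema."""


class PlacementError(HeatExposureError, ValueError):
    """A station location falls outside the grid bounds."""


class EmptyOverlapError(HeatExposureError, ValueError):
    """No paired timestamps remain after aligning two series."""


class EmptyOutputError(HeatExposureError, ValueError):
    """An operation would produce no output (e.g. no complete day window)."""


class DegenerateDesignError(HeatExposureError, ValueError):
    """A regression design matrix has no variation in the predictor."""


class SampleSizeError(HeatExposureError, ValueError):
    """Too few usable samples for a stable estimate."""


class CoverageError(HeatExposureError, ValueError):
    """A rolling window is missing one or more required days."""


class DependencyError(HeatExposureError, FileNotFoundError):
    """A pipeline stage requires an upstream output that does not exist."""
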