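"""Exception hierarchy for spherefall.

Every failure mode of the pipeline maps to a distinct exception so that the
CLI can translate them into distinct exit codes and the library user can
catch exactly what they care about.
"""


class SpherefallError(Exception):
    """Base class for all spherefall errors."""


class InvalidParameterError(SpherefallError, ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class CalibrationError(SpherefallError):
    """The calibration reference could not be located in the image."""


class DetectionError(SpherefallError):
    """Frame-level detection failed in a way statuses cannot express."""


class TooFewFramesError(SpherefallError):
    """Fewer usable frames than the minimum required for a regression."""


class DegenerateTrackError(SpherefallError):
    """Track has no time variance (all frames at the same instant)."""


class RisingSampleError(SpherefallError):
    """Fitted slope is negative: the object is not falling.

    The free-fall protocol only observes sinking samples; a rising object
    indicates a buoyant sample or residual flow and is screened out.
    """


class DegenerateDataError(SpherefallError):
    """Statistical input is constant or otherwise carries no information."""


class InsufficientDataError(SpherefallError):
    """Not enough samples / repetitions for the requested statistic."""


class SchemaError(SpherefallError):
    """A tabular input does not match the documented column schema."""


class FieldOfViewError(SpherefallError):
    """A rendered sample leaves the simulated field of view."""
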