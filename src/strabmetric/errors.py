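"""Exception hierarchy for the strabmetric pipeline."""


class StrabmetricError(Exception):
    """Base class for all package errors."""


class SpecificationError(StrabmetricError, ValueError):
    """An argument names an unknown target, preset, gaze or comparison."""


class InvalidGeometryError(StrabmetricError, ValueError):
    """Scene or model geometry violates a construction precondition."""


class DegenerateMaskError(StrabmetricError, ValueError):
    """A mask is empty or lacks the required connected components."""


class DegenerateGeometryError(StrabmetricError, ValueError):
    """Points or lines are coincident / zero-length."""


class NoReflexError(StrabmetricError, ValueError):
    """No pixel inside the limbus exceeds the absolute brightness floor."""


class GeometryInconsistencyError(StrabmetricError, ValueError):
    """Recovered geometry contradicts the eyeball model."""


class UndefinedRatioError(StrabmetricError, ZeroDivisionError):
    """A movement ratio has a zero denominator."""


class InputValidationError(StrabmetricError, ValueError):
    """A nine-gaze input set is incomplete or inconsistent."""
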