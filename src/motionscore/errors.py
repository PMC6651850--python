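"""Exception hierarchy.

Two families matter to callers: :class:`InputError` (malformed or
unusable user input; CLI exit code 2) and :class:`NumericalError`
(degenerate geometry or statistics discovered during computation; CLI
exit code 3).
"""


class MotionError(Exception):
    """Base class for all package errors."""


class InputError(MotionError):
    """The input data or configuration is unusable."""


class MissingColumn(InputError):
    """A required joint coordinate column is absent from a CSV header."""


class EmptySequence(InputError):
    """A motion sequence contains zero (valid) frames."""


class NonMonotonicTime(InputError):
    """Frame timestamps are not strictly increasing."""


class IOFailure(InputError):
    """A file could not be read or written."""


class InvalidParams(InputError):
    """Generator or perturbation parameters outside their valid range."""


class InconsistentConfig(InputError):
    """A score was requested with settings that differ from the alignment's."""


class NumericalError(MotionError):
    """Computation hit a degenerate configuration."""


class ZeroVector(NumericalError):
    """An angle was requested for a (near-)zero vector."""


class DegenerateBone(NumericalError):
    """Two connected joints are coincident (bone length below 1e-6 m)."""


class DegenerateFrame(NumericalError):
    """A frame's limb geometry does not define a body coordinate system."""


class DimensionMismatch(NumericalError):
    """Feature frames with different dimensionality were compared."""


class TooLarge(NumericalError):
    """Exhaustive path enumeration was requested beyond its size limit."""


class DegenerateFit(NumericalError):
    """Regression requested on a constant predictor."""


class DegenerateInput(NumericalError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
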