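"""Exception hierarchy shared across the package."""


class IolpostError(Exception):
    """Base class for all package errors."""


class ValidationError(IolpostError, ValueError):
    """A field value is outside its physiologically plausible range."""


class SchemaError(IolpostError, ValueError):
    """An input table does not match the documented column schema."""


class InvalidGeometryError(IolpostError, ValueError):
    """Predicted lens position is incompatible with the eye's geometry
    (ELP <= 0 or ELP >= axial length)."""


class OpticalSingularityError(IolpostError, ArithmeticError):
    """A vergence denominator vanished during thin-lens propagation."""


class DegenerateFitError(IolpostError, ValueError):
    """Regression input has no usable variation (or too few points)."""
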