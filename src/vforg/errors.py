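"""Exception hierarchy for the vforg pipeline."""


class VforgError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VforgError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateSignalError(VforgError, ValueError):
    """A signal has no usable content (all-zero / zero variance)."""


class SchemaError(VforgError, ValueError):
    """An ensemble bundle on disk violates the documented schema."""
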