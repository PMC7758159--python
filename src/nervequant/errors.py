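"""Exception hierarchy shared by all pipeline stages."""


class NervequantError(Exception):
    """Base class for all package errors."""


class ParameterError(NervequantError, ValueError):
    """A configuration value or function argument is invalid."""


class MalformedInputError(NervequantError, ValueError):
    """An input file violates the expected format."""


class DataError(NervequantError, ValueError):
    """Input data is structurally valid but unusable for the requested operation."""


class RangeError(DataError):
    """A requested time window falls outside the available data."""


class NotBimodalError(DataError):
    """A histogram could not be reduced to exactly two modes."""


class DegenerateDataWarning(UserWarning):
    """Data is technically valid but yields a degenerate result (e.g. zero spread)."""
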