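"""Exception types shared across the package."""


class CoexmodError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoexmodError):
    """An input configuration violates its invariants; names the field."""


class DataError(CoexmodError):
    """Input data cannot be processed (shape, values, or format)."""
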