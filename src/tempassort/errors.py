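"""Exception types shared across the package."""


class TempassortError(Exception):
    """Base class for package errors."""


class ConfigurationError(TempassortError, ValueError):
    """A parameter value or configuration file is invalid."""


class StructuralError(TempassortError, ValueError):
    """Graph / population containers are inconsistent (e.g. mismatched node sets)."""
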