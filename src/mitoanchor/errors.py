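"""Exception hierarchy shared across the package."""


class MitoanchorError(Exception):
    """Base class for all package errors."""


class ParseError(MitoanchorError):
    """Malformed input file (message names the offending line)."""


class ValidationError(MitoanchorError):
    """Structurally valid input violating a domain invariant."""


class ParameterError(MitoanchorError):
    """Out-of-range or inconsistent parameter value."""


class ConsistencyError(MitoanchorError):
    """Two artifacts that must agree (lengths, ids) do not."""


class ConfigError(MitoanchorError):
    """Invalid or incomplete pipeline configuration."""
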