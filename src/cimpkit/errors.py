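"""Exception hierarchy shared across the package."""


class CimpkitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CimpkitError):
    """A file could not be parsed into the expected schema."""


class ValidationError(CimpkitError):
    """Parsed data violates a domain-type invariant."""


class DegenerateInputError(CimpkitError):
    """Numerically degenerate input (zero variance, collinear controls, ...)."""


class EmptySignatureError(CimpkitError):
    """Signature selection produced no probes under the given thresholds."""


class ConfigError(CimpkitError):
    """An invalid simulation or pipeline configuration."""
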