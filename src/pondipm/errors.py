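"""Exception types shared across the package."""


class PondIPMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PondIPMError, ValueError):
    """Invalid run, scenario, or synthesis configuration."""


class SchemaError(PondIPMError, ValueError):
    """Tabular input violates the documented CSV schema.

    Messages name the offending row and column so data suppliers can
    locate the problem.
    """


class FittingError(PondIPMError, RuntimeError):
    """Regression fitting failed (degenerate design, separation, ...)."""
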