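"""Exception types shared across the pipeline."""


class CitegateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CitegateError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(CitegateError, ValueError):
    """Malformed on-disk input (matrix, names file, GMT, metadata)."""


class FitError(CitegateError, RuntimeError):
    """A statistical fit failed or is unusable (degenerate input, no convergence)."""
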