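"""Exception hierarchy shared across the package."""


class XsigmetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XsigmetaError, ValueError):
    """Invalid configuration (bad thresholds, inconsistent simulation spec, ...)."""


class FormatError(XsigmetaError, ValueError):
    """Malformed input file (missing columns, unparseable values)."""


class ValidationError(XsigmetaError, ValueError):
    """Well-formed input violating a domain invariant (duplicate genes, p > 1, ...)."""


class PipelineError(XsigmetaError, RuntimeError):
    """A pipeline stage could not run on the provided inputs."""
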