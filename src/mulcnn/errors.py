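"""Exception hierarchy shared across the package."""


class MulCNNError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MulCNNError):
    """A file could not be parsed in the declared format."""


class ValidationError(MulCNNError):
    """Input data violate a documented invariant."""


class ConfigurationError(MulCNNError):
    """A model or run configuration is internally inconsistent."""


class CheckpointError(MulCNNError):
    """A model checkpoint is missing, truncated, or of an incompatible version."""
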