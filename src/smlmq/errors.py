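"""Exception hierarchy used across the pipeline."""


class SmlmqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SmlmqError):
    """A file does not conform to an expected on-disk format."""


class ParameterError(SmlmqError, ValueError):
    """A parameter violates its documented domain."""


class EstimationError(SmlmqError):
    """An estimator cannot produce a meaningful result on this input."""
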