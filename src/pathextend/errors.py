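"""Exception hierarchy shared across the pipeline."""


class PathextendError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PathextendError):
    """A file does not conform to its expected tabular format."""


class ValidationError(PathextendError):
    """A parsed value violates a domain invariant (e.g. beta outside [0, 1])."""


class CohortError(PathextendError):
    """Sample intersection left a phenotype class empty or too small."""


class AlignmentError(PathextendError):
    """Two in-memory objects disagree on sample identity or order."""


class NetworkError(PathextendError):
    """A weighted network could not be built (e.g. no surviving edges)."""


class ConfigError(PathextendError):
    """A pipeline configuration value is missing or out of range."""
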