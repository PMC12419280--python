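"""Exception hierarchy shared across the package."""


class ExtremoseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExtremoseqError, ValueError):
    """A configuration value is missing, malformed, or out of range."""


class SelectionError(ExtremoseqError, ValueError):
    """Cohort selection cannot be satisfied (e.g. too few samples below threshold)."""


class DataError(ExtremoseqError, ValueError):
    """An input row or matrix violates its contract."""


class ClassificationError(ExtremoseqError, ValueError):
    """A variant cannot be placed in the region taxonomy."""


class FormatError(ExtremoseqError, ValueError):
    """A file does not conform to its declared format."""
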