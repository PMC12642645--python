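"""Exception hierarchy shared across the package.

``ValueError`` subclasses so callers that do not care about the distinction
can catch the builtin; the CLI maps them onto distinct exit codes.
"""


class FCCommError(ValueError):
    """Base class for all package-specific errors."""


class DataError(FCCommError):
    """Malformed or unusable input data (non-square matrix, NaN cell,
    constant ROI row, ...). Messages name the offending row/column."""


class NumericalError(FCCommError):
    """A numerical routine (eigensolver, optimizer) failed to produce a
    usable result."""


class UndefinedIndexError(FCCommError):
    """A partition-quality index is undefined for the given partition
    (e.g. silhouette with a single community)."""
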