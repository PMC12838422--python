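"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SpliceflankError`, so callers can catch one type at pipeline level.
"""


class SpliceflankError(Exception):
    """Base class for all spliceflank errors."""


class ConfigError(SpliceflankError):
    """Invalid simulation or run configuration."""


class GtfParseError(SpliceflankError):
    """Malformed GTF line; message carries the 1-based line number."""


class CoordinateError(SpliceflankError):
    """Interval with end < start, or a position outside contig bounds."""


class LayoutError(SpliceflankError):
    """Requested gene layout does not fit on the contig."""


class CapacityError(SpliceflankError):
    """More junction variants requested than (site, alt) pairs exist."""


class ValidationError(SpliceflankError):
    """Input rows violate a contract (ref mismatch, bad label, ...)."""


class EmptyInputError(SpliceflankError):
    """An operation that needs at least one record received none."""


class AnnotationError(SpliceflankError):
    """Transcript annotation unusable (e.g. CDS length not divisible by 3)."""


class OutOfCdsError(SpliceflankError):
    """Variant position does not fall inside the transcript's CDS."""


class DegenerateTableError(SpliceflankError):
    """Contingency table with a zero expected cell."""


class UndefinedPercentageError(SpliceflankError):
    """Percentage requested over an empty denominator."""
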