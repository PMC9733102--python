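"""Exception hierarchy for tissuetau.

Everything derives from :class:`TissueTauError` so callers can catch one
base class; individual subclasses mirror the distinct failure modes of
matrix I/O, ontology mapping and the statistical operations.
"""


class TissueTauError(ValueError):
    """Base class for all tissuetau errors."""


class MalformedInputError(TissueTauError):
    """Input file or array violates a basic contract (e.g. negative expression)."""


class DuplicateRecordError(TissueTauError):
    """Duplicate gene identifier in an expression table."""


class DimensionError(TissueTauError):
    """Matrix has too few tissues (tau needs n >= 2) or mismatched shapes."""


class AmbiguousMappingError(TissueTauError):
    """A child tissue is listed with two different parents."""


class MissingMappingError(TissueTauError):
    """An assigned tissue has no entry in the ontology map."""


class InsufficientDataError(TissueTauError):
    """Too few observations for the requested statistic."""


class DegenerateVarianceError(TissueTauError):
    """A variance-ratio test received a zero-variance sample."""


class InsufficientOverlapError(TissueTauError):
    """Two datasets share too few genes to correlate."""
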