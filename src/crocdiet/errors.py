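"""Exception hierarchy for diet-composition analysis."""


class CrocdietError(Exception):
    """Base class for all package errors."""


class SchemaError(CrocdietError):
    """An input file does not have the expected columns."""


class ValidationError(CrocdietError):
    """A record violates a domain invariant (negative count, unknown id, ...)."""


class OutOfRangeError(ValidationError):
    """A total length falls outside the size-class scheme."""


class NoSolutionError(CrocdietError):
    """No integer count vector is consistent with a rounded percentage column."""


class UndefinedMetricError(CrocdietError):
    """A percentage or index is undefined (zero denominator)."""


class DegenerateTestError(CrocdietError):
    """A statistical test cannot be formed (single category, single stomach, ...)."""
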