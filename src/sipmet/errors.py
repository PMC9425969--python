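"""Exception hierarchy shared by all sipmet modules."""


class SipmetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SipmetError, ValueError):
    """A numeric parameter lies outside its valid domain."""


class ShapeError(SipmetError, ValueError):
    """Array/vector dimensions are inconsistent."""


class EmptyInputError(SipmetError, ValueError):
    """An input that must contain data is empty or all-zero."""


class SelectionError(SipmetError, ValueError):
    """A fraction-window selection matched no fractions."""


class InsufficientDataError(SipmetError, ValueError):
    """Too few observations for the requested computation."""


class UndefinedEFError(SipmetError, ArithmeticError):
    """Enrichment factor undefined (zero denominator, no pseudocount)."""


class UndefinedCorrelationError(SipmetError, ValueError):
    """Correlation undefined (constant input vector)."""


class ConsistencyError(SipmetError, ValueError):
    """Cross-table references do not line up (missing sample/column)."""


class IncompleteDesignError(SipmetError, ValueError):
    """A (sex, time, replicate) cell is missing one of its composites."""


class DegenerateSampleError(SipmetError, ValueError):
    """A sample column is all zero where positive counts are required."""


class ValidationError(SipmetError, ValueError):
    """Configuration or input-bundle validation failed."""


class ParseError(SipmetError, ValueError):
    """A file failed to parse; message names file, line and field."""
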