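"""Exception hierarchy."""


class HybridmorphError(Exception):
    """Base class for all package errors."""


class SchemaError(HybridmorphError, ValueError):
    """Input table is missing required columns or is otherwise malformed."""


class ValidationError(HybridmorphError, ValueError):
    """A row violates a domain invariant (range, sign, sex code)."""


class AdjustmentError(HybridmorphError, ValueError):
    """Sex adjustment cannot be performed (missing sex, missing offset)."""


class InsufficientDataError(HybridmorphError, ValueError):
    """Too few non-missing values for the requested statistic."""


class DomainError(HybridmorphError, ValueError):
    """Argument outside its mathematical domain (e.g. ancestry not in [0,1])."""
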