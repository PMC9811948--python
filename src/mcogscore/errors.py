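"""Exception hierarchy shared across the package."""


class McogError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(McogError):
    """A subtest was presented with the wrong structure (trial count,
    congruency split, nonpositive timing)."""


class InvalidResponseError(McogError):
    """A response value lies outside the instrument's response set."""


class DegenerateReferenceError(McogError):
    """A z-score reference cannot be fitted (too few participants or
    zero variance in a subtest)."""


class UndefinedStatisticError(McogError):
    """A statistic is undefined for the given input (constant vector,
    zero margin, zero range, single-class labels)."""


class SchemaError(McogError):
    """An input table is missing required columns or malformed."""


class IntegrityError(McogError):
    """Row-level validation failed (duplicate ids, out-of-range values)."""

    def __init__(self, message: str, rows: list[str] | None = None):
        super().__init__(message)
        self.rows = rows or []
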