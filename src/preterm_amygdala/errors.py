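"""Exception hierarchy shared by all pipeline stages.

Every error raised deliberately by this package derives from
:class:`PretermAmygdalaError`, so callers (and the CLI) can distinguish
validation problems (exit code 2) from degenerate-statistics problems
(exit code 3).
"""


class PretermAmygdalaError(Exception):
    """Base class for all package errors."""


class ValidationError(PretermAmygdalaError, ValueError):
    """Invalid inputs: out-of-range values, misaligned tables, bad shapes."""


class ConfigurationError(ValidationError):
    """Invalid simulation or run configuration."""


class SampleSizeError(ValidationError):
    """Too few observations for the requested fit."""


class SingularDesignError(PretermAmygdalaError, ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


class DegenerateFitError(PretermAmygdalaError, ArithmeticError):
    """A fit whose residual scale is exactly zero (nothing to standardize)."""


class DegenerateStatisticError(PretermAmygdalaError, ArithmeticError):
    """A statistic whose defining denominator is zero (e.g. zero pooled SD)."""


class DegenerateColumnError(PretermAmygdalaError, ValueError):
    """A zero-variance column inside a group, where scaling is required."""

    def __init__(self, group: str, column: str):
        self.group = group
        self.column = column
        super().__init__(
            f"zero-variance column {column!r} in group {group!r}: "
            "cannot z-score"
        )
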