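"""Exception hierarchy.

Three broad classes map onto the CLI exit codes: input problems (exit 2),
configuration problems (exit 3) and numerical/analysis failures (exit 4).
"""


class CombotxError(Exception):
    """Base class for all package errors."""


class InputError(CombotxError):
    """Unreadable, malformed or out-of-domain input data (CLI exit 2)."""


class ConfigurationError(CombotxError):
    """Invalid parameter or pipeline configuration (CLI exit 3)."""


class NumericalError(CombotxError):
    """An analysis step failed numerically on valid input (CLI exit 4)."""


class DomainError(InputError):
    """A value lies outside the mathematical domain of an operation."""


class StructureError(InputError):
    """A table is missing a structural element (e.g. monotherapy row/column)."""


class InsufficientDataError(InputError):
    """Too few usable points for a fit."""


class DegenerateFitError(NumericalError):
    """The data carry no information about the model parameters."""


class FitFailureError(NumericalError):
    """Optimizer did not converge to an acceptable solution."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateColumnError(NumericalError):
    """A data column has zero spread, so z-scores are undefined."""


class NormalizationError(NumericalError):
    """A sample cannot be normalized (e.g. zero upper quartile)."""


class NoEvaluableCellsError(NumericalError):
    """No dose-matrix cell has a fractional effect usable for CI."""


class NoOverlapError(InputError):
    """A gene set shares no members with the ranked list."""
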