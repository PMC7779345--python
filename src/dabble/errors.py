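"""Exception hierarchy for the dabble package.

Everything derives from :class:`DabbleError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class DabbleError(Exception):
    """Base class for all dabble errors."""


class DomainError(DabbleError, ValueError):
    """An argument is outside its mathematical domain (e.g. negative dose)."""


class AxisMismatchError(DabbleError, ValueError):
    """An operation received parameters/curves on the wrong exposure axis."""


class InsufficientDataError(DabbleError, ValueError):
    """Too few points to fit the model."""


class FitError(DabbleError, RuntimeError):
    """The least-squares fit failed; carries solver diagnostics."""


class NoSolutionError(DabbleError, ValueError):
    """The survival model cannot be inverted (alpha = beta = 0)."""


class TableRangeError(DabbleError, ValueError):
    """A LET query falls outside the tabulated range and extrapolation is off."""


class MissingDataError(DabbleError, KeyError):
    """A requested time point (or column) is absent from a table."""


class UndefinedStatisticError(DabbleError, ZeroDivisionError):
    """DABBLE's denominator (the indirect death fraction) is zero."""


class ParseError(DabbleError, ValueError):
    """A delimited table failed validation; message names the offending line."""


class ValidationError(DabbleError, ValueError):
    """A domain object or simulation spec violates its invariants."""


class CurveProcessingError(DabbleError, RuntimeError):
    """One or more curves in a batch failed.

    Carries the per-curve failures and whatever results did succeed so the
    caller can report everything instead of losing the batch.
    """

    def __init__(self, failures, partial_results):
        self.failures = list(failures)          # list of (label, let, exception)
        self.partial_results = list(partial_results)
        lines = "; ".join(
            f"{label} (LET={let:g}): {exc}" for label, let, exc in self.failures
        )
        super().__init__(f"{len(self.failures)} curve(s) failed: {lines}")
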