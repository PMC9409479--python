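"""Exception hierarchy shared across the package.

Distinct classes exist so the command-line layer can map failure modes to
distinct exit codes (I/O, precondition, fit failure).
"""


class SeedwaspError(Exception):
    """Base class for package errors."""


class PreconditionError(SeedwaspError, ValueError):
    """An operation's documented precondition was violated."""


class SingularDesignError(PreconditionError):
    """Regression design matrix is singular (e.g. all temperatures equal)."""


class FitFailureError(SeedwaspError, RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class WeatherGapError(SeedwaspError, ValueError):
    """Daily weather series has a missing date; names the first gap."""

    def __init__(self, missing_date):
        super().__init__(f"weather series is missing {missing_date}")
        self.missing_date = missing_date
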