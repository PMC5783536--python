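"""Errors raised by the model-fitting routines."""


class ZigregError(Exception):
    """Base class for package errors."""


class SeparationError(ZigregError):
    """Perfect (or quasi-) separation: some coefficient diverges while the
    likelihood keeps improving; the offending column is named."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(
            f"perfect separation detected: coefficient for {column!r} diverges "
            "while the log-likelihood is still improving"
        )


class RankDeficientError(ZigregError):
    """Design matrix is not of full column rank; collinear columns listed."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class ConvergenceError(ZigregError):
    """Optimiser failed to converge within the iteration budget."""
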