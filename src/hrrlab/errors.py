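"""Exception hierarchy shared across the package."""


class HrrlabError(Exception):
    """Base class for all package errors."""


class ValidationError(HrrlabError):
    """An input violates a documented precondition."""


class InsufficientDataError(HrrlabError):
    """Not enough beats/samples to compute the requested quantity."""


class GenerationError(HrrlabError):
    """The synthetic generator produced a non-physiological rate."""


class UndefinedReserveError(HrrlabError):
    """Heart-rate reserve (peak minus rest) is non-positive."""


class RankDeficiencyError(ValidationError):
    """Design matrix is not full column rank; names offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design matrix; collinear columns: {self.columns}")


class ParseError(ValidationError):
    """A file failed validation; carries the first offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
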