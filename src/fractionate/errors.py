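"""Exception hierarchy shared across the package."""


class FractionationError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FractionationError):
    """A run configuration is inconsistent or incomplete."""


class DomainError(FractionationError, ValueError):
    """A parameter combination leaves the domain of a model law."""


class DegenerateSampleError(FractionationError, ValueError):
    """A sample is too degenerate (e.g. zero variance) to fit."""


class ParseError(FractionationError, ValueError):
    """A serialized genome or length table violates the file contract."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InferenceError(FractionationError):
    """No admissible candidate was found in the scanned sweep range.

    Carries the full candidate table so the failure can be inspected.
    """

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates if candidates is not None else []
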