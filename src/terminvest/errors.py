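"""Named exception types shared across the package."""


class TerminvestError(Exception):
    """Base class for all package errors."""


class DomainError(TerminvestError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ZeroGrowthError(DomainError):
    """Start and end densities are equal: doubling time is undefined."""


class InsufficientDataError(TerminvestError, ValueError):
    """Too few usable observations for the requested computation."""


class LengthMismatchError(TerminvestError, ValueError):
    """Paired sequences have different lengths."""


class InvalidDesignError(TerminvestError, ValueError):
    """An experiment design or generator truth table violates its invariants."""


class MalformedTableError(TerminvestError, ValueError):
    """An input table is missing columns or contains invalid rows."""


class PipelineStageError(TerminvestError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
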