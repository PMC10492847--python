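"""Exception hierarchy for the MR pipeline."""


class IvmrError(Exception):
    """Base class for all package errors."""


class FormatError(IvmrError, ValueError):
    """A file or table does not conform to the expected layout."""


class IntegrityError(IvmrError, ValueError):
    """Internal consistency violated (e.g. duplicate rsids in one table)."""


class DomainError(IvmrError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(IvmrError):
    """Too few instruments for the requested estimator or test."""

    def __init__(self, needed: int, got: int, what: str = "estimator"):
        self.needed = needed
        self.got = got
        super().__init__(f"{what} requires at least {needed} instruments, got {got}")


class FeasibilityError(IvmrError):
    """A simulation configuration cannot be realised (e.g. genome-wide
    significance unreachable at the requested sample size)."""


class PipelineStageError(IvmrError):
    """A pipeline stage depleted the instrument set; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
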