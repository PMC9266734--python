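"""Exception hierarchy for the penmark pipeline."""


class PenmarkError(Exception):
    """Base class for all penmark errors."""


class SchemaError(PenmarkError):
    """An input table is missing a required column or has an invalid value."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class ReconciliationError(PenmarkError):
    """CT table and sample annotation disagree on the sample universe."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class ConfigError(PenmarkError):
    """Invalid analysis or simulation configuration."""


class InsufficientDataError(PenmarkError):
    """Too few usable observations to compute the requested quantity."""


class StageError(PenmarkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
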