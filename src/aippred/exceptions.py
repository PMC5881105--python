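"""Exception hierarchy shared across the toolkit."""


class AippredError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(AippredError, ValueError):
    """A peptide sequence violates the validation contract."""


class ParameterError(AippredError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class ConfigurationError(AippredError):
    """A required configuration element (table, option) is missing or invalid."""


class PipelineError(AippredError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
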