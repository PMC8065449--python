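"""Exception hierarchy shared across the toolkit."""


class LitnetError(Exception):
    """Base class for all litnet errors."""


class CorpusError(LitnetError):
    """A corpus file is malformed or violates a corpus invariant."""


class SchemaError(LitnetError):
    """A tabular input is missing required columns or fields."""


class ValidationError(LitnetError):
    """A parameter set or simulation spec violates its invariants."""


class PipelineError(LitnetError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
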