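"""Exception hierarchy for pipeline input validation."""


class SexbiasevoError(Exception):
    """Base class for all package errors."""


class ParseError(SexbiasevoError):
    """A file could not be parsed in the expected dialect."""


class LookupError_(SexbiasevoError, KeyError):
    """A referenced identifier (sample, contig, gene) was not found."""


class BoundsError(SexbiasevoError, ValueError):
    """A coordinate lies outside its contig or window."""


class ReconciliationError(SexbiasevoError):
    """Two inputs that must describe the same entities disagree."""


class ValidationError(SexbiasevoError, ValueError):
    """A value violates a domain invariant (e.g. negative FPKM)."""


class ConfigError(SexbiasevoError, ValueError):
    """A configuration value is invalid."""


class StageError(SexbiasevoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
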