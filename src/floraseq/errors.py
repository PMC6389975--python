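"""Exception hierarchy shared across the pipeline stages."""


class FloraseqError(Exception):
    """Base class for all package errors."""


class ConfigError(FloraseqError):
    """An invalid configuration value; the message names the offending field."""


class LoadError(FloraseqError):
    """A malformed or inconsistent input file."""


class ComputationError(FloraseqError):
    """A numerically impossible request (zero library, empty background, ...)."""


class ContractError(FloraseqError):
    """A precondition violation on an operation's arguments."""


class PipelineError(FloraseqError):
    """A stage of the end-to-end run failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
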