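"""Exception hierarchy shared across the pipeline.

The command-line layer maps these onto exit codes (config errors,
data/parse errors, stage failures); library users catch them directly.
"""


class StemlincError(Exception):
    """Base class for all package errors."""


class ConfigError(StemlincError):
    """Invalid or inconsistent configuration."""


class DataError(StemlincError):
    """Malformed or contradictory input data."""


class ParseError(DataError):
    """A file failed to parse; the message names the file and line."""


class ConstantProfileError(DataError):
    """A correlation was requested against a constant expression vector."""


class StageError(StemlincError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
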