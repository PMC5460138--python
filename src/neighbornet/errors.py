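"""Exception hierarchy shared across the package.

Config problems and data problems are kept distinct so the command-line
layer can map them to different exit codes (2 and 3 respectively).
"""


class NeighborNetError(Exception):
    """Base class for all package errors."""


class ConfigError(NeighborNetError):
    """Invalid configuration or parameters."""


class DataError(NeighborNetError):
    """Invalid, empty or inconsistent input data."""


class ParseError(DataError):
    """Malformed file content; carries file position context in the message."""


class DegenerateInputError(DataError):
    """Input too small or too uniform for the requested statistic."""


class EmptySeedError(DataError):
    """No cancer-related protein present in the network."""


class PipelineError(NeighborNetError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
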