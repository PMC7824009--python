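"""Exception types shared across the package."""


class TetrapanelError(Exception):
    """Base class for all package errors."""


class FormatError(TetrapanelError):
    """A file or value does not conform to the expected format."""


class UndefinedStatisticError(TetrapanelError):
    """A statistic (frequency, correlation, accuracy) is undefined on the input."""


class UnreachableTargetError(TetrapanelError):
    """A requested panel size cannot be reached by thresholding.

    Attributes
    ----------
    floor_size : int
        The smallest panel size achievable (retained count at threshold 0).
    """

    def __init__(self, message: str, floor_size: int):
        super().__init__(message)
        self.floor_size = floor_size


class PipelineStageError(TetrapanelError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
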