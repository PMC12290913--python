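"""Exception hierarchy shared across the pipeline stages."""


class VitseqError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(VitseqError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(VitseqError, ValueError):
    """A file or in-memory structure is not in the expected format."""


class ShapeError(VitseqError, ValueError):
    """Array dimensions do not match the configured contract."""


class DataError(VitseqError, ValueError):
    """Labels or sample collections are inconsistent."""


class InsufficientSlicesError(VitseqError, ValueError):
    """A slice stack is shorter than the requested central window."""

    def __init__(self, n_available: int, n_requested: int):
        self.n_available = n_available
        self.n_requested = n_requested
        super().__init__(
            f"cannot select {n_requested} central slices from a stack of "
            f"{n_available}"
        )


class StratificationError(DataError):
    """A class has too few members to stratify across the requested folds."""


class DependencyError(VitseqError, RuntimeError):
    """A pipeline stage was invoked before its prerequisites exist."""


class StageError(VitseqError, RuntimeError):
    """Wraps any error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
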