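"""Exception hierarchy shared by all netbeh modules."""


class NetbehError(Exception):
    """Base class for all netbeh errors."""


class DegenerateInputError(NetbehError):
    """An input is constant / has zero variance where variation is required."""


class InsufficientDataError(NetbehError):
    """Not enough observations for the requested computation."""


class CollinearityError(NetbehError):
    """A design matrix is rank deficient."""


class SaturationError(NetbehError):
    """A correlation magnitude of 1 was passed where |r| < 1 is required."""


class IncompleteProfileError(NetbehError):
    """A diagnostic profile is missing required tasks."""


class GridMismatchError(NetbehError):
    """Volumes that must share a grid do not."""


class StageError(NetbehError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
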