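"""Exception hierarchy shared by all motoret modules."""


class MotoretError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MotoretError, ValueError):
    """An input violates a documented invariant (bad shape, range, duplicate id...)."""


class FormatError(MotoretError, IOError):
    """A file on disk is not a well-formed MRC2014 map or particle TSV."""


class UndefinedScoreError(MotoretError, ValueError):
    """A correlation score is requested over an empty Fourier support."""


class InsufficientDensityError(MotoretError, ValueError):
    """Too few voxels survive selection for a geometric fit to be meaningful."""


class PipelineStageError(MotoretError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original!r}")
        self.stage = stage
        self.original = original
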