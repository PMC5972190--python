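"""Exception hierarchy shared across the package."""


class OtomorphError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(OtomorphError, ValueError):
    """A file could not be read or written in the requested container format."""


class DimensionalityError(OtomorphError, ValueError):
    """Payload is not a 3-D scalar grid, or two grids have mismatched shapes."""


class VolumeDataError(OtomorphError, ValueError):
    """Volume samples violate an invariant (non-finite, out of range)."""


class ParameterError(OtomorphError, ValueError):
    """A filter/operator parameter violates its precondition."""


class DegenerateReferenceError(OtomorphError, ValueError):
    """Histogram-matching reference slice is constant; the quantile map is undefined."""


class PhantomSpecificationError(OtomorphError, ValueError):
    """Requested phantom geometry cannot be realised inside the volume."""


class PipelineStageError(OtomorphError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
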