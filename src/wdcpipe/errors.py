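"""Exception hierarchy shared across the pipeline."""


class WdcPipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(WdcPipeError):
    """A file could not be parsed in the expected format."""


class DimensionalityError(WdcPipeError):
    """An image array is neither 3D nor 4D, or axes are inconsistent."""


class GridMismatchError(WdcPipeError):
    """Two volumes do not share a compatible voxel grid."""


class DegenerateInputError(WdcPipeError):
    """An input is empty, constant, or otherwise carries no information."""


class DegenerateSeriesError(DegenerateInputError):
    """A voxel time series has zero variance or zero norm."""


class DegenerateMapError(DegenerateInputError):
    """A map has no spread and cannot be standardized."""


class ValidationError(WdcPipeError):
    """A value violates its declared domain (e.g. negative FD, p outside [0,1])."""


class EmptyNetworkError(WdcPipeError):
    """A network submask is empty after resampling/intersection."""


class ContainmentError(WdcPipeError):
    """A submask voxel falls outside the map's analysis mask."""


class ManifestError(WdcPipeError):
    """The session manifest is inconsistent (duplicates, unknown labels...)."""


class DesignError(WdcPipeError):
    """A model design matrix is rank deficient or otherwise unusable."""


class ComparisonError(WdcPipeError):
    """Two models were fitted on different rows and cannot be compared."""


class PermutationError(WdcPipeError):
    """Too many permutation refits failed."""
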