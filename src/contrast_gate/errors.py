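"""Named exceptions raised across the pipeline.

Every contract violation raises a distinct class so callers (and the CLI,
which maps them to exit codes) can tell configuration problems apart from
data problems.
"""


class ContrastGateError(Exception):
    """Base class for all package errors."""


class ConfigError(ContrastGateError):
    """Invalid or incomplete configuration."""


class DataError(ContrastGateError):
    """Base class for errors caused by the input data."""


class UnreadableFileError(DataError):
    """A volume or slice file could not be read."""


class NonVolumeError(DataError):
    """An input that must be a 3D volume is not 3D."""


class DimensionMismatchError(DataError):
    """Image and mask (or prediction and ground truth) shapes disagree."""


class MissingSpacingError(DataError):
    """Voxel spacing absent, nonpositive or non-finite."""


class DuplicateSliceError(DataError):
    """Two manifest entries share the same slice reference."""


class EmptyDatasetError(DataError):
    """An operation received an empty sample list."""


class EmptyLesionError(DataError):
    """A lesion mask required to be non-empty is empty."""


class EmptyBackgroundError(DataError):
    """The ipsilateral healthy-tissue region is empty."""


class DegenerateSliceError(DataError):
    """HU windowing left no usable pixels or a constant intensity set."""


class DegenerateContrastError(DataError):
    """Fisher's ratio undefined: zero variance sum or too few pixels."""


class EmptyMaskPairError(DataError):
    """Both masks empty where an overlap metric is undefined."""


class UnpairedEvaluationsError(DataError):
    """Two evaluation lists cannot be paired by slice reference."""


class DegenerateClusteringError(DataError):
    """Clustering impossible: all feature vectors identical."""


class InfeasibleContrastError(DataError):
    """Requested phantom Fisher's ratio outside the achievable range."""
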