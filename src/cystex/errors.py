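"""Exception types shared across the pipeline."""


class CystexError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CystexError, ValueError):
    """Lesion geometry does not fit the simulation grid."""


class FormatError(CystexError, ValueError):
    """An input file or series violates the expected format."""


class UnsupportedDataError(CystexError, ValueError):
    """Input data is readable but not supported (e.g. colour DICOM)."""


class EmptyROIError(CystexError, ValueError):
    """A lesion mask contains no voxels."""


class DegenerateROIError(CystexError, ValueError):
    """ROI intensities are constant; mu +/- 3 sigma windowing is undefined."""


class EmptyMatrixError(CystexError, ValueError):
    """No valid voxel pairs at the requested co-occurrence offset."""


class ParameterError(CystexError, ValueError):
    """A configuration parameter is out of its allowed range."""


class FeatureNameError(CystexError, ValueError):
    """A feature name does not match the naming grammar."""


class SingularDesignError(CystexError, ValueError):
    """Regression design matrix is rank-deficient."""

    def __init__(self, message, collinear=()):
        super().__init__(message)
        self.collinear = tuple(collinear)


class DataError(CystexError, ValueError):
    """Inconsistent tabular inputs (e.g. annotation without a truth label)."""
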