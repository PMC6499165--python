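"""Exception hierarchy for the motor-map pipeline."""


class TmsMapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TmsMapError):
    """A required column is missing from a motor-map table."""


class EmptyFileError(TmsMapError):
    """A motor-map table contains no data rows."""


class NoForegroundError(TmsMapError):
    """Head segmentation found no foreground voxels."""


class InsufficientForegroundError(TmsMapError):
    """Too few foreground voxels to sample a point cloud at the stride."""


class DegeneratePointError(TmsMapError):
    """A point coincides with the centroid; its angular coordinates are undefined."""


class InsufficientPointsError(TmsMapError):
    """Fewer points than free parameters in the ellipsoid fit."""


class SingularDesignError(TmsMapError):
    """The ellipsoid design matrix is rank deficient."""


class DegenerateCogError(TmsMapError):
    """The data center of gravity coincides with the centroid (or the pole axis)."""


class MethodError(TmsMapError):
    """Unknown cluster consolidation method."""


class DegenerateGeometryError(TmsMapError):
    """Surface-fit sites are collinear or otherwise untriangulable."""


class SingularSystemError(TmsMapError):
    """The biharmonic interpolation system is singular."""


class ZeroMassError(TmsMapError):
    """All map values are zero; the center of gravity is undefined."""


class NoPeakError(TmsMapError):
    """No grid cell exceeds the threshold; no peak region exists."""


class FrameMismatchError(TmsMapError):
    """Two datasets declare different reference coordinate frames."""


class NoOverlapError(TmsMapError):
    """No spatial overlap between the two maps; RMSE/difference undefined."""


class DegenerateTestError(TmsMapError):
    """The ROC testing set is all-positive or all-negative; TPR or FPR undefined."""
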