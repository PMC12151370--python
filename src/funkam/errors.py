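"""Exception hierarchy used across the package."""


class FunkamError(Exception):
    """Base class for all package errors."""


class DegenerateConfigurationError(FunkamError):
    """Marker cloud unusable for pose estimation (too few or collinear markers)."""


class IllPosedCenterError(FunkamError):
    """SCoRE system is rank deficient (pure hinge or no relative rotation)."""


class IllPosedAxisError(FunkamError):
    """SARA system has no isolated null direction (no hinge-like motion)."""


class DegenerateAxisError(FunkamError):
    """Joint coordinate system construction failed (axis parallel to segment line)."""


class MissingMarkerError(FunkamError):
    """A required marker label is absent from a trajectory set."""


class UnfillableGapError(FunkamError):
    """A marker gap cannot be filled rigidly (fewer than 3 visible donors)."""


class ValidationError(FunkamError):
    """Input violates a documented precondition."""
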