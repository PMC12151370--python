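"""Rigid-transform algebra and weighted SVD pose estimation.

Conventions used throughout the package:

* A :class:`RigidTransform` maps *local* (segment) coordinates to *laboratory*
  coordinates: ``p_lab = R @ p_local + t``.  The columns of ``R`` are the
  segment axes expressed in the laboratory frame.
* The laboratory frame is X anterior, Y up, Z to the subject's right.

Pose estimation follows the weighted orthogonal Procrustes solution
(Söderkvist–Wedin): centroid removal, weighted cross-covariance, SVD with a
``diag(1, 1, det)`` reflection guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConfigurationError, ValidationError

__all__ = [
    "RigidTransform",
    "PointCloud",
    "estimate_pose",
    "estimate_pose_batch",
    "rotation_offset",
    "rotation_about",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation (3x3, det +1) plus translation (m)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- validation -------------------------------------------------------
    def validate(self, tol: float = _ORTHO_TOL) -> "RigidTransform":
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=tol):
            raise ValidationError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise ValidationError("rotation determinant is not +1")
        return self

    # -- group operations -------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (n, 3) from local to lab coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    return a.invert()


@dataclass
class PointCloud:
    """Labelled marker positions for one sample.

    ``occluded`` flags markers that must be ignored by pose estimation.
    """

    labels: list[str]
    positions: np.ndarray
    occluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.positions):
            raise ValidationError("labels and positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("marker labels must be unique")
        if self.occluded is None:
            self.occluded = np.zeros(len(self.labels), dtype=bool)
        else:
            self.occluded = np.asarray(self.occluded, dtype=bool).reshape(-1)

    def select(self, labels: list[str]) -> "PointCloud":
        idx = [self.labels.index(l) for l in labels]
        return PointCloud(list(labels), self.positions[idx], self.occluded[idx])


def _check_noncollinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-8:
        raise DegenerateConfigurationError(
            "marker configuration is collinear (or coincident); pose is not unique"
        )


def estimate_pose(
    reference: PointCloud | np.ndarray,
    observed: PointCloud | np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Weighted least-squares rigid transform taking *reference* onto *observed*.

    Minimizes ``sum_i w_i || R ref_i + t - obs_i ||^2`` over proper rigid
    motions and returns the transform together with the weighted RMS residual
    (m).  Markers occluded in either cloud are dropped from the fit.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 3 usable markers, or a collinear configuration.
    """
    if isinstance(reference, PointCloud) and isinstance(observed, PointCloud):
        common = [l for l in reference.labels if l in observed.labels]
        ref_sel = reference.select(common)
        obs_sel = observed.select(common)
        usable = ~(ref_sel.occluded | obs_sel.occluded)
        ref = ref_sel.positions[usable]
        obs = obs_sel.positions[usable]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if len(weights) == len(reference.labels):
                weights = weights[[reference.labels.index(l) for l in common]]
            weights = weights[usable]
    else:
        ref = np.asarray(reference, dtype=float).reshape(-1, 3)
        obs = np.asarray(observed, dtype=float).reshape(-1, 3)

    if len(ref) != len(obs):
        raise ValidationError("reference/observed marker counts differ")
    if len(ref) < 3:
        raise DegenerateConfigurationError(
            f"need >= 3 usable markers for pose estimation, got {len(ref)}"
        )
    if weights is None:
        w = np.ones(len(ref))
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValidationError("weights must be nonnegative and not all zero")
    _check_noncollinear(ref[w > 0])

    T, rms = _procrustes(ref, obs, w)
    return T, rms


def _procrustes(ref: np.ndarray, obs: np.ndarray, w: np.ndarray) -> tuple[RigidTransform, float]:
    wsum = w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    obs_c = (w[:, None] * obs).sum(axis=0) / wsum
    A = ref - ref_c
    B = obs - obs_c
    H = (w[:, None] * B).T @ A  # 3x3 weighted cross-covariance (obs x ref)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    t = obs_c - R @ ref_c
    res = obs - (ref @ R.T + t)
    rms = float(np.sqrt((w * (res**2).sum(axis=1)).sum() / wsum))
    return RigidTransform(R, t), rms


def estimate_pose_batch(
    reference: np.ndarray, observed: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Procrustes over a stack of frames.

    Parameters
    ----------
    reference : (m, 3) local marker positions.
    observed : (f, m, 3) per-frame observations.
    weights : (m,) optional nonnegative weights.

    Returns ``(R, t, rms)`` with shapes ``(f, 3, 3)``, ``(f, 3)``, ``(f,)``.
    Assumes the caller has checked non-collinearity once.
    """
    ref = np.asarray(reference, dtype=float)
    obs = np.asarray(observed, dtype=float)
    m = ref.shape[0]
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    obs_c = (w[None, :, None] * obs).sum(axis=1) / wsum
    A = ref - ref_c
    B = obs - obs_c[:, None, :]
    H = np.einsum("m,fmi,mj->fij", w, B, A)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", U, Vt))
    D = np.zeros_like(U)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", U, D, Vt)
    t = obs_c - np.einsum("fij,j->fi", R, ref_c)
    pred = np.einsum("fij,mj->fmi", R, ref) + t[:, None, :]
    res = obs - pred
    rms = np.sqrt((w[None, :] * (res**2).sum(axis=2)).sum(axis=1) / wsum)
    return R, t, rms


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    n = np.asarray(axis, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotation_offset(frame_a: np.ndarray, frame_b: np.ndarray) -> RigidTransform:
    """Rotation-only transform ``R`` with ``R @ frame_a = frame_b``.

    Both arguments are orthonormal axis triads given as 3x3 matrices whose
    *columns* are the axes, expressed in a common frame.  Used as the fixed
    joint-frame reorientation in the functional-axis integration strategies.
    """
    A = np.asarray(frame_a, dtype=float)
    B = np.asarray(frame_b, dtype=float)
    for M, name in ((A, "frame_a"), (B, "frame_b")):
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ValidationError(f"{name} is not an orthonormal triad")
    return RigidTransform(B @ A.T, np.zeros(3))
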