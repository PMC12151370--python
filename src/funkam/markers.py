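"""Trial-level marker conditioning.

Covers rigid-body gap filling, virtual reconstruction of removed posterior
pelvic markers from their static relationship to the anterior/lateral pelvic
markers, and soft-tissue-artifact suppression with the optimal common shape
technique (OCST): an alternating Procrustes scheme that estimates the rigid
"common shape" of a marker cluster together with its per-frame poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingMarkerError, UnfillableGapError, ValidationError
from .rigid import (
    RigidTransform,
    _check_noncollinear,
    estimate_pose,
    estimate_pose_batch,
)

__all__ = [
    "MarkerTrajectorySet",
    "CommonShape",
    "fill_gaps_rigid",
    "reconstruct_virtual_markers",
    "ocst",
]


@dataclass
class MarkerTrajectorySet:
    """Labelled marker trajectories sampled on a uniform time grid.

    positions are metres with shape (frames, markers, 3); ``occluded`` flags
    samples with no valid data (their positions are ignored everywhere).
    """

    labels: list[str]
    rate: float
    positions: np.ndarray
    occluded: np.ndarray = field(default=None)  # type: ignore[assignment]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must have shape (frames, markers, 3)")
        f, m, _ = self.positions.shape
        if len(self.labels) != m:
            raise ValidationError("labels do not match marker dimension")
        if len(set(self.labels)) != m:
            raise ValidationError("marker labels must be unique")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if self.occluded is None:
            self.occluded = np.zeros((f, m), dtype=bool)
        else:
            self.occluded = np.asarray(self.occluded, dtype=bool)
            if self.occluded.shape != (f, m):
                raise ValidationError("occluded must have shape (frames, markers)")
        if self.times is None:
            self.times = np.arange(f) / self.rate
        else:
            self.times = np.asarray(self.times, dtype=float)
            dt = np.diff(self.times)
            if len(dt) and (np.any(dt <= 0) or np.max(np.abs(dt - 1.0 / self.rate)) > 1e-9):
                raise ValidationError("times must increase at 1/rate spacing")
        bad = ~np.isfinite(self.positions).all(axis=2) & ~self.occluded
        if np.any(bad):
            raise ValidationError("non-finite positions in non-occluded samples")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MissingMarkerError(f"marker {label!r} not present") from None

    def indices(self, labels: list[str]) -> list[int]:
        return [self.index(l) for l in labels]

    def subset(self, labels: list[str]) -> "MarkerTrajectorySet":
        idx = self.indices(labels)
        return MarkerTrajectorySet(
            list(labels),
            self.rate,
            self.positions[:, idx].copy(),
            self.occluded[:, idx].copy(),
            self.times.copy(),
        )

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            list(self.labels),
            self.rate,
            self.positions.copy(),
            self.occluded.copy(),
            self.times.copy(),
        )

    def frame(self, f: int, labels: list[str] | None = None):
        """Return (labels, positions, occluded) for one frame."""
        if labels is None:
            return self.labels, self.positions[f], self.occluded[f]
        idx = self.indices(labels)
        return labels, self.positions[f, idx], self.occluded[f, idx]


@dataclass
class CommonShape:
    """OCST output: a rigid cluster shape (centroid at origin) + per-frame poses."""

    labels: list[str]
    local_positions: np.ndarray
    poses: list[RigidTransform]
    rms_residual: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.local_positions = np.asarray(self.local_positions, dtype=float)
        if len(self.labels) < 3:
            raise ValidationError("a common shape needs >= 3 markers")
        c = self.local_positions.mean(axis=0)
        if np.linalg.norm(c) > 1e-9:
            raise ValidationError("common shape centroid must be at the origin")


def fill_gaps_rigid(trial: MarkerTrajectorySet, group: list[str]) -> MarkerTrajectorySet:
    """Fill occluded samples of a rigid marker group.

    A fully visible donor frame provides the group's rigid geometry; in every
    gap frame the donor cloud is posed onto the visible subset (SVD fit) and
    the missing markers are read off the posed cloud.  Samples outside the
    group, and visible samples, are returned bitwise unchanged.
    """
    idx = trial.indices(group)
    occ = trial.occluded[:, idx]
    if not occ.any():
        return trial
    full = np.where(~occ.any(axis=1))[0]
    if len(full) == 0:
        raise UnfillableGapError("no fully visible donor frame for group")
    donor = trial.positions[full[0], idx]
    _check_noncollinear(donor)
    out = trial.copy()
    gap_frames = np.where(occ.any(axis=1))[0]
    bad_frames = [int(f) for f in gap_frames if (~occ[f]).sum() < 3]
    if bad_frames:
        raise UnfillableGapError(
            f"frames with fewer than 3 visible donors in group: {bad_frames}"
        )
    for f in gap_frames:
        vis = ~occ[f]
        T, _ = estimate_pose(donor[vis], trial.positions[f, [idx[i] for i in np.where(vis)[0]]])
        posed = T.apply(donor)
        missing = np.where(occ[f])[0]
        for i in missing:
            out.positions[f, idx[i]] = posed[i]
            out.occluded[f, idx[i]] = False
    return out


def reconstruct_virtual_markers(
    trial: MarkerTrajectorySet,
    static_reference: MarkerTrajectorySet,
    donors: list[str],
    targets: list[str],
) -> MarkerTrajectorySet:
    """Append virtual markers to a trial from their static rigid relationship.

    The static reference (first visible frame) fixes the rigid geometry of
    ``donors + targets``; every trial frame poses the donors and maps the
    targets through that pose.  Used to restore the posterior pelvic markers
    removed after the reference recordings.
    """
    for lbl in targets:
        static_reference.index(lbl)
    d_idx_s = static_reference.indices(donors)
    t_idx_s = static_reference.indices(targets)
    f0 = int(np.where(~static_reference.occluded[:, d_idx_s + t_idx_s].any(axis=1))[0][0])
    donor_ref = static_reference.positions[f0, d_idx_s]
    target_ref = static_reference.positions[f0, t_idx_s]
    _check_noncollinear(donor_ref)

    d_idx = trial.indices(donors)
    existing = [l for l in targets if l in trial.labels]
    obs = trial.positions[:, d_idx]
    R, t, _ = estimate_pose_batch(donor_ref, obs)
    new_pos = np.einsum("fij,mj->fmi", R, target_ref) + t[:, None, :]

    labels = list(trial.labels)
    positions = trial.positions.copy()
    occluded = trial.occluded.copy()
    for k, lbl in enumerate(targets):
        if lbl in existing:
            j = labels.index(lbl)
            positions[:, j] = new_pos[:, k]
            occluded[:, j] = False
        else:
            labels.append(lbl)
            positions = np.concatenate([positions, new_pos[:, k : k + 1]], axis=1)
            occluded = np.concatenate(
                [occluded, np.zeros((trial.n_frames, 1), dtype=bool)], axis=1
            )
    return MarkerTrajectorySet(labels, trial.rate, positions, occluded, trial.times.copy())


def _align_shapes(a: np.ndarray, b: np.ndarray) -> float:
    """Max marker displacement between centered shapes after optimal alignment."""
    T, _ = estimate_pose(a, b)
    return float(np.max(np.linalg.norm(T.apply(a) - b, axis=1)))


def ocst(
    cluster: MarkerTrajectorySet,
    labels: list[str] | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CommonShape:
    """Optimal common shape technique.

    Alternates (a) posing the current shape to every frame and (b) updating
    the shape as the mean of the back-transformed observations, re-centered,
    until the shape change (max marker displacement after optimal alignment)
    drops below ``tol`` or ``max_iter`` is reached.  Initialized from the
    first fully visible frame.  Non-convergence sets ``converged=False``
    rather than raising.
    """
    if labels is None:
        labels = list(cluster.labels)
    if len(labels) < 3:
        raise ValidationError("OCST needs >= 3 cluster markers")
    if cluster.n_frames < 2:
        raise ValidationError("OCST needs >= 2 frames")
    idx = cluster.indices(labels)
    if cluster.occluded[:, idx].any():
        cluster = fill_gaps_rigid(cluster, labels)
    obs = cluster.positions[:, idx]  # (f, m, 3)

    shape = obs[0] - obs[0].mean(axis=0)
    _check_noncollinear(shape)
    converged = False
    rms = np.inf
    for _ in range(max_iter):
        R, t, rms_f = estimate_pose_batch(shape, obs)
        rms = float(np.sqrt(np.mean(rms_f**2)))
        back = np.einsum("fji,fmj->fmi", R, obs - t[:, None, :])  # R^T (obs - t)
        new_shape = back.mean(axis=0)
        new_shape = new_shape - new_shape.mean(axis=0)
        change = _align_shapes(shape, new_shape)
        shape = new_shape
        if change < tol:
            converged = True
            break
    R, t, rms_f = estimate_pose_batch(shape, obs)
    rms = float(np.sqrt(np.mean(rms_f**2)))
    poses = [RigidTransform(R[f], t[f]) for f in range(len(obs))]
    return CommonShape(list(labels), shape, poses, rms, converged)
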