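"""Functional joint calibration.

From dynamic reference movements this module estimates the functional hip
joint center (SCoRE: a point simultaneously fixed in two moving segment
frames, solved as one stacked linear least-squares system) and the functional
knee/ankle flexion axes (SARA: the near-null right-singular direction of the
same stacked system).  Joint centers are obtained by projecting the midpoint
of the epicondyle/malleoli markers onto the functional axis, and joint
coordinate systems are built from the axis and the segment line:

* knee:  x = unit(z x u),  u = unit(HJC - KJC),  y = unit(z x x), origin KJC
* ankle: x = unit(z x u),  u = unit(KJC - AJC),  y = unit(z x x), origin AJC

with z the functional axis oriented medial-to-lateral.  All results are
stored in carrier-marker local frames (OCST common shapes of the pelvis
markers, thigh cluster, shank cluster and foot markers) so they can be
transferred into any trial by posing the carriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import DEFAULT_LAYOUT, MarkerLayout
from .errors import (
    DegenerateAxisError,
    IllPosedAxisError,
    IllPosedCenterError,
    MissingMarkerError,
    ValidationError,
)
from .markers import CommonShape, MarkerTrajectorySet, ocst
from .rigid import RigidTransform, estimate_pose_batch

__all__ = [
    "JointFrame",
    "FunctionalCalibration",
    "TransferredFrames",
    "score",
    "sara",
    "project_midpoint_onto_axis",
    "build_knee_jcs",
    "build_ankle_jcs",
    "calibrate",
    "transfer_to_trial",
]

SCORE_ROTATION_WARN_DEG = 15.0


@dataclass
class JointFrame:
    """Origin plus right-handed orthonormal axis triad (columns x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns are x, y, z
    expressed_in: str = "lab"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-9):
            raise ValidationError("joint frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValidationError("joint frame is not right-handed")

    @property
    def x_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.axes[:, 2]

    def transformed(self, T: RigidTransform, expressed_in: str = "lab") -> "JointFrame":
        return JointFrame(T.apply(self.origin), T.rotation @ self.axes, expressed_in)


def _stack_system(
    poses_parent: list[RigidTransform], poses_child: list[RigidTransform]
) -> tuple[np.ndarray, np.ndarray]:
    f = len(poses_parent)
    if f != len(poses_child):
        raise ValidationError("parent/child pose counts differ")
    if f < 3:
        raise ValidationError("need >= 3 frames")
    A = np.zeros((3 * f, 6))
    b = np.zeros(3 * f)
    for i, (Tp, Tc) in enumerate(zip(poses_parent, poses_child)):
        A[3 * i : 3 * i + 3, :3] = Tp.rotation
        A[3 * i : 3 * i + 3, 3:] = -Tc.rotation
        b[3 * i : 3 * i + 3] = Tc.translation - Tp.translation
    return A, b


def _relative_rotation_range(
    poses_parent: list[RigidTransform], poses_child: list[RigidTransform]
) -> float:
    """Largest geodesic angle (rad) between relative orientations in the trial."""
    rels = [Tp.rotation.T @ Tc.rotation for Tp, Tc in zip(poses_parent, poses_child)]
    R0 = rels[0]
    angles = []
    for R in rels:
        c = (np.trace(R0.T @ R) - 1.0) / 2.0
        angles.append(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(np.max(angles))


def _residual(poses_parent, poses_child, c_p, c_c) -> float:
    d = [
        Tp.apply(c_p) - Tc.apply(c_c) for Tp, Tc in zip(poses_parent, poses_child)
    ]
    return float(np.sqrt(np.mean(np.sum(np.asarray(d) ** 2, axis=1))))


def score(
    poses_parent: list[RigidTransform], poses_child: list[RigidTransform]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Symmetrical center of rotation estimation.

    Solves ``R_p c_p + t_p = R_c c_c + t_c`` over all frames in the
    least-squares sense and returns the center in the parent and child local
    frames plus the RMS residual (m).

    Raises :class:`IllPosedCenterError` for rank-deficient systems (pure hinge
    motion or no relative rotation).
    """
    A, b = _stack_system(poses_parent, poses_child)
    s = np.linalg.svd(A, compute_uv=False)
    if s[5] / s[0] < 1e-8:
        raise IllPosedCenterError(
            "relative motion does not determine a unique center "
            "(hinge-like or absent relative rotation)"
        )
    rng = _relative_rotation_range(poses_parent, poses_child)
    if np.degrees(rng) < SCORE_ROTATION_WARN_DEG:
        warnings.warn(
            f"total relative rotation {np.degrees(rng):.1f} deg < "
            f"{SCORE_ROTATION_WARN_DEG} deg; center estimate may be unstable",
            stacklevel=2,
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    c_p, c_c = x[:3], x[3:]
    return c_p, c_c, _residual(poses_parent, poses_child, c_p, c_c)


@dataclass
class SaraResult:
    point_parent: np.ndarray
    dir_parent: np.ndarray
    point_child: np.ndarray
    dir_child: np.ndarray
    rms_residual: float

    def flipped(self) -> "SaraResult":
        return SaraResult(
            self.point_parent,
            -self.dir_parent,
            self.point_child,
            -self.dir_child,
            self.rms_residual,
        )


def sara(
    poses_parent: list[RigidTransform], poses_child: list[RigidTransform]
) -> SaraResult:
    """Symmetrical axis of rotation approach.

    The hinge axis direction is the right-singular vector of the smallest
    singular value of the stacked SCoRE system (its near-null direction),
    split into the parent/child halves and normalized.  Axis points come from
    the minimum-norm particular solution, reported as the point on each local
    axis closest to the respective cluster centroid (the local origin for
    OCST shapes).

    Raises :class:`IllPosedAxisError` when no isolated null direction exists
    (ball-joint motion, or no relative rotation at all).
    """
    A, b = _stack_system(poses_parent, poses_child)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[4] / s[0] < 1e-10 or s[4] < 2.0 * s[5] or s[5] / s[0] > 0.2:
        raise IllPosedAxisError(
            "no isolated near-null direction: relative motion is not hinge-like"
        )
    v = Vt[5]
    n_p, n_c = v[:3], v[3:]
    if np.linalg.norm(n_p) < 1e-6 or np.linalg.norm(n_c) < 1e-6:
        raise IllPosedAxisError("degenerate null direction")
    n_p = n_p / np.linalg.norm(n_p)
    n_c = n_c / np.linalg.norm(n_c)
    # particular solution with the null direction suppressed
    coef = (U.T @ b)[:5] / s[:5]
    x = Vt[:5].T @ coef
    c_p, c_c = x[:3], x[3:]
    rms = _residual(poses_parent, poses_child, c_p, c_c)
    c_p = c_p - np.dot(c_p, n_p) * n_p
    c_c = c_c - np.dot(c_c, n_c) * n_c
    return SaraResult(c_p, n_p, c_c, n_c, rms)


def project_midpoint_onto_axis(
    m_medial: np.ndarray, m_lateral: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray
) -> np.ndarray:
    """Orthogonal projection of the marker midpoint onto a joint axis."""
    n = np.asarray(axis_dir, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValidationError("axis_dir must be unit length")
    p = np.asarray(axis_point, dtype=float)
    mid = (np.asarray(m_medial, dtype=float) + np.asarray(m_lateral, dtype=float)) / 2.0
    return p + np.dot(mid - p, n) * n


def _build_jcs(origin: np.ndarray, toward: np.ndarray, z: np.ndarray) -> JointFrame:
    z = np.asarray(z, dtype=float)
    u = np.asarray(toward, dtype=float) - np.asarray(origin, dtype=float)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise DegenerateAxisError("joint centers coincide")
    u = u / nu
    x = np.cross(z, u)
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise DegenerateAxisError("functional axis is parallel to the segment line")
    x = x / nx
    y = np.cross(z, x)
    y = y / np.linalg.norm(y)
    return JointFrame(origin, np.column_stack([x, y, z]))


def build_knee_jcs(kjc: np.ndarray, hjc: np.ndarray, z_knee: np.ndarray) -> JointFrame:
    """Knee JCS: x = unit(z x (HJC - KJC)), y = unit(z x x), origin at the KJC."""
    return _build_jcs(kjc, hjc, z_knee)


def build_ankle_jcs(ajc: np.ndarray, kjc: np.ndarray, z_ankle: np.ndarray) -> JointFrame:
    """Ankle JCS: x = unit(z x (KJC - AJC)), y = unit(z x x), origin at the AJC."""
    return _build_jcs(ajc, kjc, z_ankle)


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------

CARRIERS = ("pelvis", "thigh", "shank", "foot")


@dataclass
class FunctionalCalibration:
    """All functional joint parameters, stored in carrier-marker local frames."""

    shapes: dict  # carrier name -> CommonShape
    hjc_in_pelvis: np.ndarray
    hjc_in_thigh: np.ndarray
    knee_axis: dict  # {"thigh": (point, dir), "shank": (point, dir)} local frames
    ankle_axis: dict  # {"shank": (point, dir), "foot": (point, dir)}
    kjc_local: dict  # {"thigh": p, "shank": p}
    ajc_local: dict  # {"shank": p, "foot": p}
    jcs_knee_local: dict  # carrier -> JointFrame in carrier frame ("thigh", "shank")
    jcs_ankle_local: dict  # ("shank", "foot")
    kjc: np.ndarray  # lab, static pose
    ajc: np.ndarray
    hjc: np.ndarray
    jcs_knee: JointFrame  # lab, static pose
    jcs_ankle: JointFrame
    # lab axes at the static pose expressed in the pelvis carrier frame
    # (anatomical pelvis triad; the subject stands erect in the static trial)
    pelvis_axes_local: np.ndarray = field(default_factory=lambda: np.eye(3))
    # same for every carrier: anatomical (lab-at-static) triad per carrier
    anatomic_axes_local: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)
    schema_version: int = 1

    def identity_like(self) -> bool:
        return False


def _carrier_pose_static(
    shape: CommonShape, static: MarkerTrajectorySet, frame: int = 0
) -> RigidTransform:
    idx = static.indices(shape.labels)
    R, t, _ = estimate_pose_batch(
        shape.local_positions, static.positions[frame : frame + 1, idx]
    )
    return RigidTransform(R[0], t[0])


def _poses_in_trial(shape: CommonShape, trial: MarkerTrajectorySet) -> list[RigidTransform]:
    idx = trial.indices(shape.labels)
    R, t, _ = estimate_pose_batch(shape.local_positions, trial.positions[:, idx])
    return [RigidTransform(R[f], t[f]) for f in range(trial.n_frames)]


def calibrate(
    reference_trials: dict,
    static_reference: MarkerTrajectorySet,
    layout: MarkerLayout = DEFAULT_LAYOUT,
) -> FunctionalCalibration:
    """Run the full functional calibration.

    ``reference_trials`` must contain ``"stararc"`` (hip reference),
    ``"knee"`` and ``"ankle"`` flexion references as
    :class:`MarkerTrajectorySet`.  OCST common shapes are estimated for the
    pelvis markers, thigh/shank clusters and foot markers; poses of those
    shapes feed SCoRE (hip) and SARA (knee/ankle).  Everything is expressed
    at the static reference pose and stored in carrier local frames.
    """
    for key in ("stararc", "knee", "ankle"):
        if key not in reference_trials:
            raise ValidationError(f"reference_trials missing {key!r}")
    missing = [
        l
        for l in layout.required_for_calibration()
        if l not in static_reference.labels
    ]
    if missing:
        raise MissingMarkerError(f"static reference lacks markers: {missing}")

    stararc: MarkerTrajectorySet = reference_trials["stararc"]
    knee_trial: MarkerTrajectorySet = reference_trials["knee"]
    ankle_trial: MarkerTrajectorySet = reference_trials["ankle"]

    shapes = {
        "pelvis": ocst(stararc, list(layout.pelvis_markers)),
        "thigh": ocst(knee_trial, list(layout.thigh_cluster)),
        "shank": ocst(knee_trial, list(layout.shank_cluster)),
        "foot": ocst(ankle_trial, list(layout.foot_carrier)),
    }

    # SCoRE: pelvis vs thigh during the StarArc
    pelvis_poses = shapes["pelvis"].poses
    thigh_star = _poses_in_trial(shapes["thigh"], stararc)
    hjc_in_pelvis, hjc_in_thigh, hip_rms = score(pelvis_poses, thigh_star)

    # SARA: thigh vs shank during knee flexion; shank vs foot during ankle flexion
    knee_res = sara(shapes["thigh"].poses, shapes["shank"].poses)
    shank_ankle = _poses_in_trial(shapes["shank"], ankle_trial)
    foot_ankle = shapes["foot"].poses
    ankle_res = sara(shank_ankle, foot_ankle)

    # static pose of every carrier
    Ts = {c: _carrier_pose_static(shapes[c], static_reference) for c in CARRIERS}

    def lab_axis(res: SaraResult, carrier: str, side: str):
        T = Ts[carrier]
        p = res.point_parent if side == "parent" else res.point_child
        d = res.dir_parent if side == "parent" else res.dir_child
        return T.apply(p), T.rotation @ d

    # orient axes medial -> lateral using the static landmark markers
    _, stat_pos, _ = static_reference.frame(0)

    def static_marker(lbl: str) -> np.ndarray:
        return static_reference.positions[0, static_reference.index(lbl)]

    knee_p, knee_d = lab_axis(knee_res, "thigh", "parent")
    med_lat = static_marker(layout.epicondyles[0]) - static_marker(layout.epicondyles[1])
    if np.dot(knee_d, med_lat) < 0:
        knee_res = knee_res.flipped()
        knee_d = -knee_d
    ankle_p, ankle_d = lab_axis(ankle_res, "shank", "parent")
    med_lat_a = static_marker(layout.malleoli[0]) - static_marker(layout.malleoli[1])
    if np.dot(ankle_d, med_lat_a) < 0:
        ankle_res = ankle_res.flipped()
        ankle_d = -ankle_d

    hjc_lab = Ts["pelvis"].apply(hjc_in_pelvis)
    kjc_lab = project_midpoint_onto_axis(
        static_marker(layout.epicondyles[1]),
        static_marker(layout.epicondyles[0]),
        knee_p,
        knee_d,
    )
    ajc_lab = project_midpoint_onto_axis(
        static_marker(layout.malleoli[1]),
        static_marker(layout.malleoli[0]),
        ankle_p,
        ankle_d,
    )
    jcs_knee = build_knee_jcs(kjc_lab, hjc_lab, knee_d)
    jcs_ankle = build_ankle_jcs(ajc_lab, kjc_lab, ankle_d)

    def to_local(T: RigidTransform, point=None, direction=None, frame: JointFrame | None = None):
        Ti = T.invert()
        if frame is not None:
            return JointFrame(Ti.apply(frame.origin), Ti.rotation @ frame.axes, "carrier")
        if direction is not None:
            return Ti.rotation @ direction
        return Ti.apply(point)

    knee_axis = {
        "thigh": (knee_res.point_parent, knee_res.dir_parent),
        "shank": (knee_res.point_child, knee_res.dir_child),
    }
    ankle_axis = {
        "shank": (ankle_res.point_parent, ankle_res.dir_parent),
        "foot": (ankle_res.point_child, ankle_res.dir_child),
    }
    kjc_local = {c: to_local(Ts[c], point=kjc_lab) for c in ("thigh", "shank")}
    ajc_local = {c: to_local(Ts[c], point=ajc_lab) for c in ("shank", "foot")}
    jcs_knee_local = {c: to_local(Ts[c], frame=jcs_knee) for c in ("thigh", "shank")}
    jcs_ankle_local = {c: to_local(Ts[c], frame=jcs_ankle) for c in ("shank", "foot")}

    return FunctionalCalibration(
        shapes=shapes,
        hjc_in_pelvis=hjc_in_pelvis,
        hjc_in_thigh=hjc_in_thigh,
        knee_axis=knee_axis,
        ankle_axis=ankle_axis,
        kjc_local=kjc_local,
        ajc_local=ajc_local,
        jcs_knee_local=jcs_knee_local,
        jcs_ankle_local=jcs_ankle_local,
        kjc=kjc_lab,
        ajc=ajc_lab,
        hjc=hjc_lab,
        jcs_knee=jcs_knee,
        jcs_ankle=jcs_ankle,
        pelvis_axes_local=Ts["pelvis"].rotation.T.copy(),
        anatomic_axes_local={c: Ts[c].rotation.T.copy() for c in CARRIERS},
        residuals={
            "hip_score": hip_rms,
            "knee_sara": knee_res.rms_residual,
            "ankle_sara": ankle_res.rms_residual,
            "ocst": {c: shapes[c].rms_residual for c in CARRIERS},
        },
    )


@dataclass
class TransferredFrames:
    """Per-frame lab-frame joint parameters transferred into a trial."""

    times: np.ndarray
    carrier_R: dict  # carrier -> (F, 3, 3)
    carrier_t: dict  # carrier -> (F, 3)
    hjc: np.ndarray  # (F, 3)
    kjc: np.ndarray
    ajc: np.ndarray
    jcs_knee_prox: np.ndarray  # (F, 3, 3) carried by the thigh cluster
    jcs_knee_dist: np.ndarray  # carried by the shank cluster
    jcs_ankle_prox: np.ndarray  # carried by the shank cluster
    jcs_ankle_dist: np.ndarray  # carried by the foot markers
    fit_rms: dict  # carrier -> (F,)


def transfer_to_trial(
    cal: FunctionalCalibration, trial: MarkerTrajectorySet
) -> TransferredFrames:
    """Map stored joint parameters into every frame of a trial.

    Each carrier cluster is posed against its common shape frame by frame;
    stored local joint centers and JCS triads ride along.
    """
    R = {}
    t = {}
    rms = {}
    for c in CARRIERS:
        shape = cal.shapes[c]
        idx = trial.indices(shape.labels)
        Rc, tc, rc = estimate_pose_batch(shape.local_positions, trial.positions[:, idx])
        R[c], t[c], rms[c] = Rc, tc, rc

    def point(carrier: str, p_local: np.ndarray) -> np.ndarray:
        return np.einsum("fij,j->fi", R[carrier], p_local) + t[carrier]

    def triad(carrier: str, axes_local: np.ndarray) -> np.ndarray:
        return np.einsum("fij,jk->fik", R[carrier], axes_local)

    return TransferredFrames(
        times=trial.times.copy(),
        carrier_R=R,
        carrier_t=t,
        hjc=point("pelvis", cal.hjc_in_pelvis),
        kjc=point("thigh", cal.kjc_local["thigh"]),
        ajc=point("shank", cal.ajc_local["shank"]),
        jcs_knee_prox=triad("thigh", cal.jcs_knee_local["thigh"].axes),
        jcs_knee_dist=triad("shank", cal.jcs_knee_local["shank"].axes),
        jcs_ankle_prox=triad("shank", cal.jcs_ankle_local["shank"].axes),
        jcs_ankle_dist=triad("foot", cal.jcs_ankle_local["foot"].axes),
        fit_rms=rms,
    )
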