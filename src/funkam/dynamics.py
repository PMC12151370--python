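"""Newton-Euler inverse dynamics and external joint moments.

The inward pass accumulates, for every joint, the net load of the distal
subtree (inertial terms, segment weights, and the applied force-plate
wrench).  Reported joint moments follow the *external* convention: the
moment exerted on the distal segment system by gravity, inertia and external
loads about the joint center — the standard convention for the external knee
adduction moment (EAM), adduction-positive for the right knee.

The EAM itself is extracted as the external generalized force of the knee
frontal-plane (adduction) coordinate, i.e. the moment component about the
floating adduction axis of the joint-coordinate-system rotation sequence.
When the knee internal-rotation angle is zero this equals the frontal-plane
component of the moment expressed in the distal knee joint frame
(:func:`express_moment_distal`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import DEFAULT_LAYOUT, MarkerLayout, SEGMENT_TABLE
from .calibration import FunctionalCalibration, TransferredFrames, transfer_to_trial
from .errors import ValidationError
from .kinematics import KinematicState, propagate
from .markers import MarkerTrajectorySet
from .model import Anthropometry, Model
from .rigid import rotation_about
from .signals import butterworth_zero_lag, differentiate

G = 9.81  # m/s^2, magnitude used for body weight

__all__ = [
    "AppliedWrench",
    "WrenchSeries",
    "MomentSeries",
    "IDResult",
    "newton_euler_id",
    "subtree_external_moment",
    "power_balance",
    "express_moment_distal",
    "normalize_bwht",
    "denormalize_bwht",
    "inverse_dynamics_trial",
    "floating_adduction_axis",
    "ref_pipeline",
    "resample_wrench",
]


@dataclass
class AppliedWrench:
    """External load on one segment: force (N) + couple (N·m) at a lab point."""

    segment: str
    force: np.ndarray
    moment: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        self.point = np.asarray(self.point, dtype=float).reshape(3)


@dataclass
class WrenchSeries:
    """Force-plate wrench time series expressed in the lab frame."""

    times: np.ndarray
    force: np.ndarray  # (F, 3) N
    moment: np.ndarray  # (F, 3) N·m free couple at the application point
    application_point: np.ndarray  # (F, 3) m (center of pressure)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float).reshape(-1, 3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(-1, 3)
        self.application_point = np.asarray(self.application_point, dtype=float).reshape(-1, 3)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("wrench times must be strictly increasing")
        if not (
            len(self.times) == len(self.force) == len(self.moment) == len(self.application_point)
        ):
            raise ValidationError("wrench series lengths differ")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))

    def sample(self, t: float) -> AppliedWrench:
        def interp(arr):
            return np.array([np.interp(t, self.times, arr[:, k]) for k in range(3)])

        return AppliedWrench("calcaneus", interp(self.force), interp(self.moment), interp(self.application_point))

    def interpolated(self, times: np.ndarray) -> "WrenchSeries":
        times = np.asarray(times, dtype=float)

        def interp(arr):
            return np.column_stack(
                [np.interp(times, self.times, arr[:, k]) for k in range(3)]
            )

        return WrenchSeries(times, interp(self.force), interp(self.moment), interp(self.application_point))


def resample_wrench(ws: WrenchSeries, target_rate: float, cutoff_hz: float = 6.0) -> WrenchSeries:
    """Anti-aliased resampling of a high-rate wrench to the kinematic grid.

    Low-pass filters force/moment/point with the zero-lag Butterworth used
    for the kinematics, then interpolates onto the target grid.
    """
    f = butterworth_zero_lag(ws.force, ws.rate, cutoff_hz)
    m = butterworth_zero_lag(ws.moment, ws.rate, cutoff_hz)
    p = butterworth_zero_lag(ws.application_point, ws.rate, cutoff_hz)
    smoothed = WrenchSeries(ws.times, f, m, p)
    t_new = np.arange(ws.times[0], ws.times[-1] + 1e-12, 1.0 / target_rate)
    return smoothed.interpolated(t_new)


# ---------------------------------------------------------------------------
# core Newton-Euler pass
# ---------------------------------------------------------------------------


@dataclass
class IDResult:
    tau: np.ndarray  # internal generalized forces, one per coordinate
    external_generalized: np.ndarray  # -tau
    joint_force: dict  # joint -> external force (N, lab)
    joint_moment: dict  # joint -> external moment about joint center (N·m, lab)
    joint_center: dict  # joint -> lab point the moment refers to
    state: KinematicState


def _segment_wrenches(model: Model, state: KinematicState, external, gravity) -> dict:
    """Per-segment net load (force, moment-about-world-origin), lab frame."""
    ext_by_seg: dict[str, list[AppliedWrench]] = {}
    for w in external or []:
        ext_by_seg.setdefault(w.segment, []).append(w)
    out = {}
    for name, seg in model.segments.items():
        st = state.segments[name]
        I_w = st.R @ seg.inertia @ st.R.T
        f = seg.mass * st.a_com - seg.mass * gravity
        n = (
            I_w @ st.alpha
            + np.cross(st.w, I_w @ st.w)
            + np.cross(st.com, seg.mass * st.a_com)
            - np.cross(st.com, seg.mass * gravity)
        )
        for w in ext_by_seg.get(name, []):
            f = f - w.force
            n = n - (w.moment + np.cross(w.point, w.force))
        out[name] = (f, n)
    return out


def newton_euler_id(
    model: Model,
    q: np.ndarray,
    qdot: np.ndarray | None = None,
    qddot: np.ndarray | None = None,
    external: list[AppliedWrench] | AppliedWrench | None = None,
    gravity: np.ndarray | None = None,
    state: KinematicState | None = None,
) -> IDResult:
    """Inverse dynamics at one instant.

    Outward pass: segment kinematics from ``(q, qdot, qddot)``.  Inward pass:
    subtree loads accumulated from the most distal segments; generalized
    force per coordinate is the transmitted moment (force) projected on the
    coordinate's instantaneous axis.
    """
    if isinstance(external, AppliedWrench):
        external = [external]
    g = model.gravity if gravity is None else np.asarray(gravity, dtype=float)
    if state is None:
        state = propagate(model, q, qdot, qddot)
    seg_wrench = _segment_wrenches(model, state, external, g)

    # subtree accumulation (segments are topologically ordered)
    sub_f: dict[str, np.ndarray] = {}
    sub_n: dict[str, np.ndarray] = {}
    for name in reversed(model.segment_order):
        f, n = seg_wrench[name]
        f = f.copy()
        n = n.copy()
        for ch in model.children[name]:
            f += sub_f[ch]
            n += sub_n[ch]
        sub_f[name], sub_n[name] = f, n

    n_coords = model.n_coordinates
    tau = np.zeros(n_coords)
    for i, info in enumerate(state.coords):
        joint = model.joint_by_name[info.joint]
        F = sub_f[joint.child]
        N = sub_n[joint.child]
        if info.kind == "rot":
            tau[i] = info.axis_w @ (N - np.cross(info.point_w, F))
        else:
            tau[i] = info.axis_w @ F
        if info.coupling_dir_w is not None:
            tau[i] += info.coupling_dir_w @ F

    joint_force = {}
    joint_moment = {}
    joint_center = {}
    for j in model.joints:
        st = state.segments[j.child]
        o = st.p + st.R @ j.child_placement.translation
        joint_center[j.name] = o
        joint_force[j.name] = -sub_f[j.child]
        joint_moment[j.name] = -(sub_n[j.child] - np.cross(o, sub_f[j.child]))
    return IDResult(tau, -tau, joint_force, joint_moment, joint_center, state)


def subtree_external_moment(
    model: Model,
    state: KinematicState,
    joint_name: str,
    external: list[AppliedWrench] | None = None,
    gravity: np.ndarray | None = None,
) -> np.ndarray:
    """External joint moment by direct summation over the distal subtree.

    Independent of the recursive inward pass: sums gravity, applied-load and
    momentum-rate moments of all segments distal to the joint about the joint
    center.  Used as a cross-check oracle for :func:`newton_euler_id`.
    """
    g = model.gravity if gravity is None else np.asarray(gravity, dtype=float)
    joint = model.joint_by_name[joint_name]
    st_child = state.segments[joint.child]
    o = st_child.p + st_child.R @ joint.child_placement.translation
    distal = set(model.subtree(joint.child))
    M = np.zeros(3)
    for name in distal:
        seg = model.segments[name]
        st = state.segments[name]
        I_w = st.R @ seg.inertia @ st.R.T
        M += np.cross(st.com - o, seg.mass * g)
        M -= I_w @ st.alpha + np.cross(st.w, I_w @ st.w)
        M -= np.cross(st.com - o, seg.mass * st.a_com)
    for w in external or []:
        if w.segment in distal:
            M += np.cross(w.point - o, w.force) + w.moment
    return M


def power_balance(
    model: Model,
    state: KinematicState,
    tau: np.ndarray,
    external: list[AppliedWrench] | None = None,
    gravity: np.ndarray | None = None,
) -> tuple[float, float]:
    """Return ``(sum tau·qdot, dKE/dt - P_gravity - P_external)``.

    For a consistent inverse-dynamics solution the two numbers are equal.
    """
    g = model.gravity if gravity is None else np.asarray(gravity, dtype=float)
    p_joint = float(np.dot(tau, state.qdot))
    dke = 0.0
    p_grav = 0.0
    for name, seg in model.segments.items():
        st = state.segments[name]
        I_w = st.R @ seg.inertia @ st.R.T
        dke += seg.mass * st.v_com @ st.a_com + st.w @ (I_w @ st.alpha)
        p_grav += seg.mass * g @ st.v_com
    p_ext = 0.0
    for w in external or []:
        st = state.segments[w.segment]
        v_p = st.v_com + np.cross(st.w, w.point - st.com)
        p_ext += w.force @ v_p + w.moment @ st.w
    return p_joint, dke - p_grav - p_ext


# ---------------------------------------------------------------------------
# moment expression and normalization
# ---------------------------------------------------------------------------


def express_moment_distal(moment_lab: np.ndarray, distal_axes: np.ndarray) -> np.ndarray:
    """Express a lab-frame moment in a distal joint frame (columns = axes)."""
    return np.asarray(distal_axes, dtype=float).T @ np.asarray(moment_lab, dtype=float)


def floating_adduction_axis(prox_axes: np.ndarray, flexion_rad: float) -> np.ndarray:
    """Lab direction of the knee adduction axis after the flexion rotation.

    ``prox_axes`` are the proximal (femur-side) knee joint frame axes in the
    lab (columns x, y, z).  The rotation sequence is flexion about -z, then
    adduction about -x of the rotated frame.
    """
    A = np.asarray(prox_axes, dtype=float)
    return A @ rotation_about(np.array([0.0, 0.0, -1.0]), flexion_rad) @ np.array([-1.0, 0.0, 0.0])


@dataclass
class MomentSeries:
    """Per-joint external moments plus the scalar EAM trace.

    ``joint_moment_lab`` holds lab-frame 3-vectors per joint; ``sagittal``
    holds the flexion/dorsiflexion components used in reporting; ``eam`` is
    the knee adduction moment.  Units are N·m (``units='Nm'``) or %BWHt.
    """

    times: np.ndarray
    joint_moment_lab: dict  # joint -> (F, 3)
    eam: np.ndarray  # (F,)
    sagittal: dict = field(default_factory=dict)  # name -> (F,)
    units: str = "Nm"

    def scaled(self, factor: float, units: str) -> "MomentSeries":
        return MomentSeries(
            self.times.copy(),
            {k: v * factor for k, v in self.joint_moment_lab.items()},
            self.eam * factor,
            {k: v * factor for k, v in self.sagittal.items()},
            units,
        )


def normalize_bwht(moments: MomentSeries, anthro: Anthropometry) -> MomentSeries:
    """Normalize moments to % body weight x body height: 100·M/(m·g·h)."""
    if moments.units == "%BWHt":
        return moments
    return moments.scaled(100.0 / (anthro.mass * G * anthro.height), "%BWHt")


def denormalize_bwht(moments: MomentSeries, anthro: Anthropometry) -> MomentSeries:
    if moments.units == "Nm":
        return moments
    return moments.scaled(anthro.mass * G * anthro.height / 100.0, "Nm")


def inverse_dynamics_trial(
    model: Model,
    traj,
    wrench: WrenchSeries | None,
    contact_segment: str = "calcaneus",
    anthro: Anthropometry | None = None,
) -> MomentSeries:
    """Run Newton-Euler ID over a solved coordinate trajectory.

    The wrench series is linearly interpolated onto the kinematic time base
    (resample first with :func:`resample_wrench` if rates differ a lot).
    Returns raw N·m moments unless ``anthro`` is given, in which case the
    series is %BWHt-normalized.
    """
    nf = len(traj.times)
    ws = wrench.interpolated(traj.times) if wrench is not None else None
    i_add = model.coord_index["knee_adduction"]
    i_flex = model.coord_index["knee_flexion"]
    i_ankle = model.coord_index["ankle_dorsiflexion"]
    i_hip = model.coord_index["hip_flexion"]
    moments = {j.name: np.zeros((nf, 3)) for j in model.joints}
    eam = np.zeros(nf)
    sagittal = {
        "knee_flexion_moment": np.zeros(nf),
        "ankle_dorsiflexion_moment": np.zeros(nf),
        "hip_flexion_moment": np.zeros(nf),
    }
    for f in range(nf):
        ext = None
        if ws is not None:
            ext = [
                AppliedWrench(
                    contact_segment, ws.force[f], ws.moment[f], ws.application_point[f]
                )
            ]
        qd = traj.qdot[f] if traj.qdot is not None else None
        qdd = traj.qddot[f] if traj.qddot is not None else None
        res = newton_euler_id(model, traj.q[f], qd, qdd, ext)
        for jname in moments:
            moments[jname][f] = res.joint_moment[jname]
        eam[f] = res.external_generalized[i_add]
        sagittal["knee_flexion_moment"][f] = res.external_generalized[i_flex]
        sagittal["ankle_dorsiflexion_moment"][f] = res.external_generalized[i_ankle]
        sagittal["hip_flexion_moment"][f] = res.external_generalized[i_hip]
    out = MomentSeries(np.asarray(traj.times).copy(), moments, eam, sagittal, "Nm")
    if anthro is not None:
        out = normalize_bwht(out, anthro)
    return out


# ---------------------------------------------------------------------------
# REF pipeline: moments directly from transferred functional frames
# ---------------------------------------------------------------------------

_SIGNED_SEQ = ((0.0, 0.0, -1.0), (-1.0, 0.0, 0.0), (0.0, -1.0, 0.0))


def decompose_zxy(Q: np.ndarray) -> tuple[float, float, float]:
    """Angles (flexion, adduction, rotation) of Q = Rz(-a) Rx(-b) Ry(-c)."""
    Q = np.asarray(Q, dtype=float)
    # standard ZXY decomposition Q = Rz(az) Rx(ax) Ry(ay)
    ax = np.arcsin(np.clip(Q[2, 1], -1.0, 1.0))
    az = np.arctan2(-Q[0, 1], Q[1, 1])
    ay = np.arctan2(-Q[2, 0], Q[2, 2])
    return -az, -ax, -ay


def _angular_kinematics(R_series: np.ndarray, rate: float):
    """Angular velocity/acceleration (lab) from a rotation time series."""
    Rdot = differentiate(R_series.reshape(len(R_series), 9), rate, "central").reshape(
        -1, 3, 3
    )
    W = np.einsum("fij,fkj->fik", Rdot, R_series)  # Rdot R^T, skew
    w = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)
    alpha = differentiate(w, rate, "central")
    return w, alpha


def ref_pipeline(
    trial: MarkerTrajectorySet,
    cal: FunctionalCalibration,
    wrench: WrenchSeries | None,
    anthro: Anthropometry,
    layout: MarkerLayout = DEFAULT_LAYOUT,
    transferred: TransferredFrames | None = None,
) -> tuple[dict, MomentSeries]:
    """Reference (REF) joint angles and moments from functional frames.

    No generalized-coordinate model is involved: per frame, the transferred
    functional joint centers and JCS triads define the segment frames, joint
    angles come from relative JCS orientations, and external moments are the
    direct subtree sums (plate wrench + segment weights + momentum-rate
    terms) about the transferred joint centers.  Segment inertial parameters
    come from the same anthropometric table as the scaled models, with the
    thigh/shank/foot lengths taken from the transferred joint centers.

    Returns ``(angles, moments)`` where ``angles`` maps names to radians
    series and ``moments`` is %BWHt-normalized.
    """
    tf = transferred if transferred is not None else transfer_to_trial(cal, trial)
    nf = len(tf.times)
    rate = trial.rate
    ws = wrench.interpolated(tf.times) if wrench is not None else None

    hjc, kjc, ajc = tf.hjc, tf.kjc, tf.ajc
    # segment masses and com positions
    m_shank = SEGMENT_TABLE["shank"][0] * anthro.mass
    m_thigh = SEGMENT_TABLE["thigh"][0] * anthro.mass
    foot_fracs = [SEGMENT_TABLE[s][0] for s in ("talus", "calcaneus", "toes")]
    m_foot = sum(foot_fracs) * anthro.mass
    com_thigh = hjc + 0.433 * (kjc - hjc)
    com_shank = kjc + 0.433 * (ajc - kjc)
    # lumped foot (talus+calcaneus+toes) com offset from the AJC, from the
    # generic parameter table, scaled by the heel-to-metatarsal span
    from .anthropometry import JOINT_GEOMETRY, MARKER_TABLE

    heel = trial.positions[0, trial.index("HEEL")]
    mt2 = trial.positions[0, trial.index("MT2")]
    gen_span = np.linalg.norm(
        np.asarray(MARKER_TABLE["HEEL"][1]) - np.asarray(MARKER_TABLE["MT2"][1])
    )
    s_foot = float(np.linalg.norm(heel - mt2)) / gen_span
    sub_t = np.asarray(JOINT_GEOMETRY["subtalar"][2])
    mtp_t = np.asarray(JOINT_GEOMETRY["mtp"][2])
    com_anat = (
        SEGMENT_TABLE["talus"][0] * np.zeros(3)
        + SEGMENT_TABLE["calcaneus"][0] * (sub_t + np.asarray(SEGMENT_TABLE["calcaneus"][1]))
        + SEGMENT_TABLE["toes"][0] * (sub_t + mtp_t + np.asarray(SEGMENT_TABLE["toes"][1]))
    ) / sum(foot_fracs)
    # carry the anatomic offset with the foot markers: anatomical triad at
    # time t is R_foot(t) @ (lab axes at static expressed in the carrier)
    A_foot = cal.anatomic_axes_local.get("foot", np.eye(3))
    foot_triad = np.einsum("fij,jk->fik", tf.carrier_R["foot"], A_foot)
    com_foot = ajc + np.einsum("fij,j->fi", foot_triad, com_anat * s_foot)

    # angular kinematics of the anatomical triads; linear of the coms
    w_th, al_th = _angular_kinematics(tf.jcs_knee_prox, rate)
    w_sh, al_sh = _angular_kinematics(tf.jcs_knee_dist, rate)
    w_ft, al_ft = _angular_kinematics(tf.jcs_ankle_dist, rate)
    a_com = {
        "thigh": differentiate(com_thigh, rate, "central", order=2),
        "shank": differentiate(com_shank, rate, "central", order=2),
        "foot": differentiate(com_foot, rate, "central", order=2),
    }

    def inertia_world(triads, gyr, mass):
        I_loc = np.diag(mass * np.asarray(gyr) ** 2)
        return np.einsum("fij,jk,flk->fil", triads, I_loc, triads)

    L_th = float(np.linalg.norm(hjc[0] - kjc[0]))
    L_sh = float(np.linalg.norm(kjc[0] - ajc[0]))
    I_th = inertia_world(tf.jcs_knee_prox, (0.329 * L_th, 0.149 * L_th, 0.329 * L_th), m_thigh)
    I_sh = inertia_world(tf.jcs_knee_dist, (0.255 * L_sh, 0.103 * L_sh, 0.249 * L_sh), m_shank)
    I_ft = inertia_world(tf.jcs_ankle_dist, (0.05, 0.05, 0.05), m_foot)

    g = np.array([0.0, -G, 0.0])

    def momentum_moment(o, com, mass, I_w, w, al, a):
        """Rate-of-change-of-momentum minus gravity moment about o, per frame."""
        M = np.cross(com - o, mass * (g[None, :] - a))
        M -= np.einsum("fij,fj->fi", I_w, al) + np.cross(w, np.einsum("fij,fj->fi", I_w, w))
        return M

    plate_m = np.zeros((nf, 3))
    if ws is not None:
        def plate_about(o):
            return np.cross(ws.application_point - o, ws.force) + ws.moment
    else:
        def plate_about(o):
            return plate_m

    M_knee = (
        plate_about(kjc)
        + momentum_moment(kjc, com_shank, m_shank, I_sh, w_sh, al_sh, a_com["shank"])
        + momentum_moment(kjc, com_foot, m_foot, I_ft, w_ft, al_ft, a_com["foot"])
    )
    M_ankle = plate_about(ajc) + momentum_moment(
        ajc, com_foot, m_foot, I_ft, w_ft, al_ft, a_com["foot"]
    )
    M_hip = (
        plate_about(hjc)
        + momentum_moment(hjc, com_thigh, m_thigh, I_th, w_th, al_th, a_com["thigh"])
        + momentum_moment(hjc, com_shank, m_shank, I_sh, w_sh, al_sh, a_com["shank"])
        + momentum_moment(hjc, com_foot, m_foot, I_ft, w_ft, al_ft, a_com["foot"])
    )

    # joint angles from relative JCS orientations (signed Z-X-Y sequence)
    knee_angles = np.zeros((nf, 3))
    for f in range(nf):
        Q = tf.jcs_knee_prox[f].T @ tf.jcs_knee_dist[f]
        knee_angles[f] = decompose_zxy(Q)
    ankle_flex = np.zeros(nf)
    for f in range(nf):
        Qa = tf.jcs_ankle_prox[f].T @ tf.jcs_ankle_dist[f]
        # hinge: dorsiflexion about +z of the ankle JCS
        ankle_flex[f] = np.arctan2(Qa[1, 0], Qa[0, 0])

    eam = np.zeros(nf)
    knee_flex_m = np.zeros(nf)
    ankle_m = np.zeros(nf)
    hip_m = np.zeros(nf)
    pelvis_axes = getattr(cal, "pelvis_axes_local", None)
    for f in range(nf):
        a_add = floating_adduction_axis(tf.jcs_knee_prox[f], knee_angles[f, 0])
        eam[f] = M_knee[f] @ a_add
        knee_flex_m[f] = M_knee[f] @ (tf.jcs_knee_prox[f] @ np.array([0.0, 0.0, -1.0]))
        ankle_m[f] = M_ankle[f] @ (tf.jcs_ankle_prox[f] @ np.array([0.0, 0.0, 1.0]))
        if pelvis_axes is not None:
            Rp = tf.carrier_R["pelvis"][f] @ pelvis_axes
            hip_m[f] = M_hip[f] @ (Rp @ np.array([0.0, 0.0, 1.0]))
        else:
            hip_m[f] = M_hip[f] @ np.array([0.0, 0.0, 1.0])

    angles = {
        "knee_flexion": knee_angles[:, 0],
        "knee_adduction": knee_angles[:, 1],
        "knee_rotation": knee_angles[:, 2],
        "ankle_dorsiflexion": ankle_flex,
    }
    moments = MomentSeries(
        tf.times.copy(),
        {"knee": M_knee, "ankle": M_ankle, "hip": M_hip},
        eam,
        {
            "knee_flexion_moment": knee_flex_m,
            "ankle_dorsiflexion_moment": ankle_m,
            "hip_flexion_moment": hip_m,
        },
        "Nm",
    )
    return angles, normalize_bwht(moments, anthro)
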