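"""Synthetic subjects and trials with known ground truth.

The generator builds a subject as a scaled instance of the generic model
whose knee/ankle joint frames may be deliberately tilted away from the
generic orientation (emulating the discrepancy between functional and
generic joint axes that the pipeline is designed to absorb).  Reference
movements (StarArc hip calibration, knee/ankle flexion sweeps), a static
standing reference, and static/dynamic leg-press trials are rendered through
forward kinematics, optionally corrupted with Gaussian marker noise, a
low-frequency sinusoidal soft-tissue-artifact field per cluster, and random
occlusions.

Leg-press trials also return the applied plate wrench and the ground-truth
joint moments, computed by direct subtree summation on the true kinematic
state (independent of the recursive Newton-Euler pass they are used to
check).  Study conditions are the generator defaults: 100 Hz markers, static
pushes at 60 % of a maximum voluntary contraction at three foot positions
(neutral, 12 degrees eversion, 12 degrees inversion), and dynamic extensions
at 0.025 m/s spanning 80 to 40 degrees of knee flexion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import (
    DEFAULT_LAYOUT,
    GENERIC_HEIGHT,
    GENERIC_MASS,
    PLATE_CONTACT_LOCAL,
    MarkerLayout,
)
from .calibration import build_ankle_jcs, build_knee_jcs
from .dynamics import (
    AppliedWrench,
    MomentSeries,
    WrenchSeries,
    floating_adduction_axis,
    normalize_bwht,
    subtree_external_moment,
)
from .errors import ValidationError
from .ik import CoordinateTrajectory
from .kinematics import batch_segment_poses, propagate
from .markers import MarkerTrajectorySet
from .model import Anthropometry, Model, apply_scaling, make_generic_model
from .rigid import RigidTransform, rotation_about

__all__ = [
    "NoiseSpec",
    "SyntheticSubject",
    "LegPressTrial",
    "make_subject",
    "render_markers",
    "simulate_static",
    "simulate_stararc",
    "simulate_flexion_reference",
    "simulate_legpress",
]

MVC_FORCE_N = 1200.0  # configurable maximum voluntary contraction proxy
STATIC_EFFORT = 0.60  # static trials push at 60 % MVC
LEGPRESS_SPEED = 0.025  # m/s, dynamic plate speed
STATIC_HIP_DEG = 80.0
STATIC_KNEE_DEG = 50.0
DYNAMIC_KNEE_RANGE_DEG = (80.0, 40.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Marker corruption model (all amplitudes in metres)."""

    gaussian_sigma: float = 0.0
    sta_amplitude: float = 0.0
    sta_frequency: float = 0.25  # Hz, slow skin-sliding component
    occlusion_rate: float = 0.0
    # anatomical landmark markers (epicondyles, malleoli) sit on mobile skin
    # and carry proportionally more artifact than the taped clusters — the
    # reason landmark markers get low IK weights
    landmark_sigma_factor: float = 3.0

    def __post_init__(self) -> None:
        if min(
            self.gaussian_sigma,
            self.sta_amplitude,
            self.sta_frequency,
            self.occlusion_rate,
            self.landmark_sigma_factor,
        ) < 0:
            raise ValidationError("noise parameters must be nonnegative")

    @property
    def silent(self) -> bool:
        return self.gaussian_sigma == 0 and self.sta_amplitude == 0 and self.occlusion_rate == 0


NOISELESS = NoiseSpec()


@dataclass
class SyntheticSubject:
    """A subject with fully known model, axes, and marker geometry."""

    seed: int
    anthro: Anthropometry
    model: Model  # true model, including any axis tilts
    knee_tilt_deg: tuple
    ankle_tilt_deg: tuple
    scale_factors: dict
    layout: MarkerLayout = field(default_factory=lambda: DEFAULT_LAYOUT)

    @property
    def true_knee_axes(self) -> np.ndarray:
        """True knee JCS axes in the lab at the neutral pose."""
        return self.model.joint_by_name["knee"].parent_placement.rotation

    @property
    def true_ankle_axes(self) -> np.ndarray:
        return self.model.joint_by_name["ankle"].parent_placement.rotation

    def joint_centers_neutral(self) -> dict:
        state = propagate(self.model, np.zeros(self.model.n_coordinates))
        return {
            "hjc": state.segments["thigh"].p.copy(),
            "kjc": state.segments["shank"].p.copy(),
            "ajc": state.segments["talus"].p.copy(),
        }


def _tilt_pair(tilt) -> tuple[float, float]:
    if np.isscalar(tilt):
        return (float(tilt), 0.0)
    t = tuple(float(x) for x in tilt)
    if len(t) != 2:
        raise ValidationError("axis tilt must be a scalar or (about_x, about_y) pair")
    return t


def make_subject(
    seed: int,
    knee_tilt_deg=0.0,
    ankle_tilt_deg=0.0,
    anthro: Anthropometry | None = None,
    segment_scale_jitter: float = 0.02,
) -> SyntheticSubject:
    """Create a deterministic synthetic subject.

    Anthropometry is sampled around the study population (mass 64 +/- 8.3 kg,
    height 1.74 +/- 0.052 m) unless given explicitly.  ``knee_tilt_deg`` /
    ``ankle_tilt_deg`` tilt the functional flexion axis away from the generic
    medio-lateral direction, as a rotation about the lab anterior (x) axis or
    an ``(about_x, about_y)`` pair; zero tilt (the default) makes the
    functional axes coincide with the generic ones.
    """
    rng = np.random.default_rng(seed)
    if anthro is None:
        mass = float(np.clip(rng.normal(GENERIC_MASS, 8.3), 40.0, 110.0))
        height = float(np.clip(rng.normal(GENERIC_HEIGHT, 0.052), 1.45, 2.05))
        anthro = Anthropometry(mass, height)
    base = anthro.height / GENERIC_HEIGHT
    jit = lambda: float(rng.normal(1.0, segment_scale_jitter))  # noqa: E731
    s_pelvis = base * jit()
    s_foot = base * jit()
    factors = {
        "pelvis": s_pelvis,
        "torso": s_pelvis,
        "thigh": base * jit(),
        "shank": base * jit(),
        "talus": s_foot,
        "calcaneus": s_foot,
        "toes": s_foot,
    }
    model = apply_scaling(make_generic_model(), factors, anthro)

    kt = _tilt_pair(knee_tilt_deg)
    at = _tilt_pair(ankle_tilt_deg)
    state = propagate(model, np.zeros(model.n_coordinates))
    hjc = state.segments["thigh"].p
    kjc = state.segments["shank"].p
    ajc = state.segments["talus"].p

    def tilted_z(pair):
        R = rotation_about([1.0, 0.0, 0.0], np.radians(pair[0])) @ rotation_about(
            [0.0, 1.0, 0.0], np.radians(pair[1])
        )
        return R @ np.array([0.0, 0.0, 1.0])

    knee = model.joint_by_name["knee"]
    J_knee = build_knee_jcs(kjc, hjc, tilted_z(kt))
    knee.parent_placement = RigidTransform(J_knee.axes, knee.parent_placement.translation)
    knee.child_placement = RigidTransform(J_knee.axes, knee.child_placement.translation)
    ankle = model.joint_by_name["ankle"]
    J_ankle = build_ankle_jcs(ajc, kjc, tilted_z(at))
    ankle.parent_placement = RigidTransform(J_ankle.axes, ankle.parent_placement.translation)
    ankle.child_placement = RigidTransform(J_ankle.axes, ankle.child_placement.translation)
    model._index()
    return SyntheticSubject(seed, anthro, model, kt, at, factors)


# ---------------------------------------------------------------------------
# marker rendering
# ---------------------------------------------------------------------------

_CLUSTERS = {
    "pelvis": DEFAULT_LAYOUT.pelvis_markers,
    "thigh": DEFAULT_LAYOUT.thigh_cluster,
    "shank": DEFAULT_LAYOUT.shank_cluster,
    "foot": DEFAULT_LAYOUT.foot_carrier,
}


def render_markers(
    subject: SyntheticSubject,
    q_series: np.ndarray,
    rate: float,
    noise: NoiseSpec = NOISELESS,
    rng: np.random.Generator | None = None,
    include_psis: bool = True,
) -> MarkerTrajectorySet:
    """Forward-kinematics rendering of the subject's markers."""
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    model = subject.model
    labels = [l for l in model.marker_labels() if include_psis or l not in subject.layout.psis_markers]
    seg_of = {l: model.marker_segment(l) for l in labels}
    nf = len(q_series)
    pos = np.empty((nf, len(labels), 3))
    poses = batch_segment_poses(model, q_series)
    for i, lbl in enumerate(labels):
        R, p = poses[seg_of[lbl]]
        pos[:, i] = p + np.einsum("fij,j->fi", R, model.segments[seg_of[lbl]].local_markers[lbl])

    occluded = np.zeros((nf, len(labels)), dtype=bool)
    if not noise.silent:
        t = np.arange(nf) / rate
        if noise.sta_amplitude > 0:
            for cluster in _CLUSTERS.values():
                phase = rng.uniform(0, 2 * np.pi)
                for lbl in cluster:
                    if lbl not in labels:
                        continue
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    wave = noise.sta_amplitude * np.sin(
                        2 * np.pi * noise.sta_frequency * t + phase + rng.uniform(0, 0.8)
                    )
                    pos[:, labels.index(lbl)] += wave[:, None] * d
        if noise.gaussian_sigma > 0:
            landmarks = set(subject.layout.epicondyles) | set(subject.layout.malleoli)
            sigma = np.array(
                [
                    noise.gaussian_sigma
                    * (noise.landmark_sigma_factor if l in landmarks else 1.0)
                    for l in labels
                ]
            )
            pos += rng.normal(size=pos.shape) * sigma[None, :, None]
        if noise.occlusion_rate > 0:
            occluded = rng.random((nf, len(labels))) < noise.occlusion_rate
    return MarkerTrajectorySet(labels, rate, pos, occluded)


def _q_template(model: Model, **values) -> np.ndarray:
    q = np.zeros(model.n_coordinates)
    for name, v in values.items():
        q[model.coord_index[name]] = v
    return q


def _smooth_bump(u: np.ndarray) -> np.ndarray:
    """0 -> 1 -> 0 over u in [0, 1], C1-smooth."""
    return np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2


def simulate_static(
    subject: SyntheticSubject,
    duration: float = 1.0,
    rate: float = 100.0,
    noise: NoiseSpec = NOISELESS,
    rng: np.random.Generator | None = None,
) -> MarkerTrajectorySet:
    """Neutral standing static reference (all coordinates zero)."""
    nf = max(int(round(duration * rate)), 1)
    q = np.zeros((nf, subject.model.n_coordinates))
    return render_markers(subject, q, rate, noise, rng)


def simulate_stararc(
    subject: SyntheticSubject,
    amplitude_deg: float = 40.0,
    duration: float = 10.0,
    rate: float = 100.0,
    noise: NoiseSpec = NOISELESS,
    rng: np.random.Generator | None = None,
) -> MarkerTrajectorySet:
    """StarArc hip reference: flexion/abduction rays plus a circumduction arc."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    nf = int(round(duration * rate))
    t = np.arange(nf) / rate
    u = t / duration
    A = np.radians(amplitude_deg)
    flex = np.zeros(nf)
    add = np.zeros(nf)
    # five rays over the first 70 % of the trial
    ray_dirs = np.radians([0.0, 45.0, 90.0, 135.0, 180.0])
    for k, th in enumerate(ray_dirs):
        lo, hi = 0.14 * k, 0.14 * (k + 1)
        seg = (u >= lo) & (u < hi)
        bump = _smooth_bump((u[seg] - lo) / 0.14)
        flex[seg] += A * np.cos(th) * bump
        add[seg] += 0.6 * A * np.sin(th) * bump
    # circumduction arc over the last 30 %
    seg = u >= 0.7
    phi = 2 * np.pi * (u[seg] - 0.7) / 0.3
    ramp = _smooth_bump((u[seg] - 0.7) / 0.3)
    flex[seg] += 0.5 * A * np.cos(phi) * ramp
    add[seg] += 0.5 * A * np.sin(phi) * ramp

    model = subject.model
    q = np.zeros((nf, model.n_coordinates))
    q[:, model.coord_index["hip_flexion"]] = flex
    q[:, model.coord_index["hip_adduction"]] = add
    q[:, model.coord_index["knee_flexion"]] = np.radians(15.0)  # slight knee bend
    return render_markers(subject, q, rate, noise, rng)


def simulate_flexion_reference(
    subject: SyntheticSubject,
    joint: str = "knee",
    sweep_deg: tuple | None = None,
    duration: float = 6.0,
    rate: float = 100.0,
    cycles: int = 2,
    noise: NoiseSpec = NOISELESS,
    rng: np.random.Generator | None = None,
) -> MarkerTrajectorySet:
    """Active knee or ankle flexion sweep for the SARA axis estimate."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if joint not in ("knee", "ankle"):
        raise ValidationError("joint must be 'knee' or 'ankle'")
    if sweep_deg is None:
        sweep_deg = (5.0, 85.0) if joint == "knee" else (-20.0, 25.0)
    lo, hi = np.radians(sweep_deg[0]), np.radians(sweep_deg[1])
    nf = int(round(duration * rate))
    t = np.arange(nf) / rate
    angle = lo + (hi - lo) * 0.5 * (1 - np.cos(2 * np.pi * cycles * t / duration))
    model = subject.model
    q = np.zeros((nf, model.n_coordinates))
    q[:, model.coord_index["hip_flexion"]] = np.radians(30.0)
    if joint == "knee":
        q[:, model.coord_index["knee_flexion"]] = angle
    else:
        q[:, model.coord_index["knee_flexion"]] = np.radians(30.0)
        q[:, model.coord_index["ankle_dorsiflexion"]] = angle
    return render_markers(subject, q, rate, noise, rng)


# ---------------------------------------------------------------------------
# leg-press trials with ground truth
# ---------------------------------------------------------------------------


@dataclass
class LegPressTrial:
    condition: str
    foot_position: str
    markers: MarkerTrajectorySet
    wrench: WrenchSeries
    truth: MomentSeries  # %BWHt, from the independent subtree-sum oracle
    q_true: CoordinateTrajectory
    anthro: Anthropometry


def _foot_tilt_deg(foot_position: str) -> float:
    table = {"neutral": 0.0, "eversion12": 12.0, "inversion12": -12.0}
    if foot_position not in table:
        raise ValidationError(f"unknown foot position {foot_position!r}")
    return table[foot_position]


def _legpress_posture(model: Model, hip_deg: float, knee_deg: float, ankle_deg: float = 10.0):
    return _q_template(
        model,
        pelvis_ty=0.60,
        hip_flexion=np.radians(hip_deg),
        knee_flexion=np.radians(knee_deg),
        ankle_dorsiflexion=np.radians(ankle_deg),
    )


def _dynamic_q_of_t(model: Model, L1: float, L2: float, hjc_like=None):
    """Closed-form planar ray kinematics for the dynamic extension.

    The hip-to-ankle distance grows linearly in time along a fixed ray from
    the hip, the knee angle follows from the law of cosines, and the foot
    keeps its lab orientation.  Returns (q_of_t, duration, speed_actual).
    """
    k0, k1 = np.radians(DYNAMIC_KNEE_RANGE_DEG)

    def r_of_k(k):
        return np.sqrt(L1**2 + L2**2 + 2 * L1 * L2 * np.cos(k))

    r0, r1 = r_of_k(k0), r_of_k(k1)

    def beta(k, r):
        return np.arcsin(np.clip(L2 * np.sin(k) / r, -1.0, 1.0))

    h0 = np.radians(STATIC_HIP_DEG)
    psi = h0 - beta(k0, r0)  # fixed ray angle
    a0 = np.radians(10.0)
    foot_angle0 = h0 - k0 + a0

    def q_of_t(t, duration, speed):
        # r extends smoothly beyond [r0, r1]; no clamping, so the finite
        # differences used for the ground-truth derivatives stay clean at
        # the first and last grid samples
        t = np.atleast_1d(np.asarray(t, dtype=float))
        r = r0 + speed * t
        k = np.arccos(np.clip((r**2 - L1**2 - L2**2) / (2 * L1 * L2), -1.0, 1.0))
        h = psi + beta(k, r)
        a = foot_angle0 - (h - k)
        q = np.zeros((len(t), model.n_coordinates))
        q[:, model.coord_index["pelvis_ty"]] = 0.60
        q[:, model.coord_index["hip_flexion"]] = h
        q[:, model.coord_index["knee_flexion"]] = k
        q[:, model.coord_index["ankle_dorsiflexion"]] = a
        return q

    return q_of_t, r0, r1


def simulate_legpress(
    subject: SyntheticSubject,
    condition: str = "static",
    foot_position: str = "neutral",
    rate: float = 100.0,
    duration: float = 3.0,
    noise: NoiseSpec = NOISELESS,
    rng: np.random.Generator | None = None,
    mvc_force: float = MVC_FORCE_N,
    peak_force: float | None = None,
    speed: float = LEGPRESS_SPEED,
) -> LegPressTrial:
    """Simulate one leg-press trial and its ground-truth moments.

    Static: the posture holds 80 degrees hip / 50 degrees knee flexion while
    the plate force ramps up (0.5 s) to 60 % MVC and stays on that plateau.
    Dynamic: constant-speed extension along a fixed ray spanning 80 to 40
    degrees of knee flexion.  The plate force acts at the foot contact point,
    directed from the contact point towards the hip center, tilted in the
    frontal plane by +/-12 degrees for the everted/inverted foot positions.

    The returned ``truth`` series is computed by direct momentum-balance
    subtree sums on the true state and is the oracle for the model pipelines.
    The posterior pelvic markers are excluded from the trial (they are
    removed after the reference recordings and must be reconstructed).
    """
    model = subject.model
    tilt = np.radians(_foot_tilt_deg(foot_position))
    if rng is None:
        rng = np.random.default_rng(subject.seed + 7919)

    if condition == "static":
        if duration <= 1.6:
            raise ValidationError("static trials need > 1.6 s for a 1 s plateau")
        nf = int(round(duration * rate))
        times = np.arange(nf) / rate
        q0 = _legpress_posture(model, STATIC_HIP_DEG, STATIC_KNEE_DEG)
        q = np.tile(q0, (nf, 1))
        qd = np.zeros_like(q)
        qdd = np.zeros_like(q)
        ramp = np.clip(times / 0.5, 0.0, 1.0)
        magnitude = STATIC_EFFORT * mvc_force * (3 * ramp**2 - 2 * ramp**3)
    elif condition == "dynamic":
        state0 = propagate(model, np.zeros(model.n_coordinates))
        L1 = float(np.linalg.norm(state0.segments["thigh"].p - state0.segments["shank"].p))
        L2 = float(np.linalg.norm(state0.segments["shank"].p - state0.segments["talus"].p))
        q_of_t, r0, r1 = _dynamic_q_of_t(model, L1, L2)
        T = (r1 - r0) / speed
        nf = int(np.ceil(T * rate)) + 1
        T_grid = (nf - 1) / rate
        speed_actual = (r1 - r0) / T_grid  # last sample lands exactly on 40 deg
        times = np.arange(nf) / rate
        q = q_of_t(times, T_grid, speed_actual)
        h = 1e-4
        qp = q_of_t(times + h, T_grid, speed_actual)
        qm = q_of_t(times - h, T_grid, speed_actual)
        qd = (qp - qm) / (2 * h)
        qdd = (qp - 2 * q + qm) / h**2
        ramp = np.clip(times / (0.25 * T_grid), 0.0, 1.0)
        peak = peak_force if peak_force is not None else 0.5 * mvc_force
        magnitude = peak * (3 * ramp**2 - 2 * ramp**3)
    else:
        raise ValidationError("condition must be 'static' or 'dynamic'")

    # plate wrench and ground-truth moments on the true state
    nq = len(q)
    cop = np.zeros((nq, 3))
    force = np.zeros((nq, 3))
    couple = np.zeros((nq, 3))
    eam = np.zeros(nq)
    knee_m = np.zeros((nq, 3))
    ankle_m = np.zeros((nq, 3))
    hip_m = np.zeros((nq, 3))
    sag = {k: np.zeros(nq) for k in ("knee_flexion_moment", "ankle_dorsiflexion_moment", "hip_flexion_moment")}
    i_kflex = model.coord_index["knee_flexion"]
    tilt_R = rotation_about([1.0, 0.0, 0.0], tilt)
    knee_joint = model.joint_by_name["knee"]
    ankle_joint = model.joint_by_name["ankle"]
    hip_joint = model.joint_by_name["hip"]
    for f in range(nq):
        state = propagate(model, q[f], qd[f], qdd[f])
        st_c = state.segments["calcaneus"]
        p = st_c.p + st_c.R @ PLATE_CONTACT_LOCAL
        hjc = state.segments["thigh"].p
        u = hjc - p
        u = u / np.linalg.norm(u)
        F = magnitude[f] * (tilt_R @ u)
        cop[f], force[f] = p, F
        ext = [AppliedWrench("calcaneus", F, np.zeros(3), p)]
        Mk = subtree_external_moment(model, state, "knee", ext)
        Ma = subtree_external_moment(model, state, "ankle", ext)
        Mh = subtree_external_moment(model, state, "hip", ext)
        knee_m[f], ankle_m[f], hip_m[f] = Mk, Ma, Mh
        prox_knee = state.segments["thigh"].R @ knee_joint.parent_placement.rotation
        eam[f] = Mk @ floating_adduction_axis(prox_knee, q[f, i_kflex])
        sag["knee_flexion_moment"][f] = Mk @ (prox_knee @ np.array([0.0, 0.0, -1.0]))
        prox_ankle = state.segments["shank"].R @ ankle_joint.parent_placement.rotation
        sag["ankle_dorsiflexion_moment"][f] = Ma @ (prox_ankle @ np.array([0.0, 0.0, 1.0]))
        prox_hip = state.segments["pelvis"].R @ hip_joint.parent_placement.rotation
        sag["hip_flexion_moment"][f] = Mh @ (prox_hip @ np.array([0.0, 0.0, 1.0]))

    wrench = WrenchSeries(times.copy(), force, couple, cop)
    truth = normalize_bwht(
        MomentSeries(times.copy(), {"knee": knee_m, "ankle": ankle_m, "hip": hip_m}, eam, sag, "Nm"),
        subject.anthro,
    )
    markers = render_markers(subject, q, rate, noise, rng, include_psis=False)
    q_true = CoordinateTrajectory(
        list(model.coordinate_names), times.copy(), q, qd, qdd,
        np.zeros(nq), np.zeros(nq, dtype=bool),
    )
    return LegPressTrial(condition, foot_position, markers, wrench, truth, q_true, subject.anthro)
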