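"""Weighted least-squares inverse kinematics.

Each frame minimizes ``sum_i w_i ||obs_i - fk_i(q)||^2`` with a damped
(Levenberg-style) Gauss-Newton iteration on the analytic marker Jacobian.
Trials are solved frame by frame with warm starting, then the coordinate
series is optionally low-pass filtered before differentiation.

Marker weights default to 1.0 for tracking/cluster markers and 0.1 for
anatomical landmark markers (epicondyles and malleoli), which constrain
single points rather than segment rotations; the ratio is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import DEFAULT_LAYOUT, MarkerLayout
from .errors import ValidationError
from .kinematics import marker_jacobian, propagate
from .rigid import rotation_about
from .markers import MarkerTrajectorySet
from .model import Model
from .signals import FilterSpec, differentiate

__all__ = [
    "CoordinateTrajectory",
    "default_marker_weights",
    "solve_ik_frame",
    "solve_ik_trial",
]

LANDMARK_WEIGHT = 0.1
MAX_ITER = 100
STEP_TOL = 1e-8
OBJ_TOL = 1e-12


@dataclass
class CoordinateTrajectory:
    """Generalized-coordinate time series (radians / metres internally)."""

    names: list[str]
    times: np.ndarray
    q: np.ndarray  # (frames, n)
    qdot: np.ndarray | None = None
    qddot: np.ndarray | None = None
    fit_rms: np.ndarray | None = None
    flags: np.ndarray | None = None  # True where the frame did not converge

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.times), len(self.names)):
            raise ValidationError("q must have shape (frames, n_coordinates)")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))

    def column(self, name: str) -> np.ndarray:
        return self.q[:, self.names.index(name)]


def default_marker_weights(
    labels: list[str],
    layout: MarkerLayout = DEFAULT_LAYOUT,
    landmark_weight: float = LANDMARK_WEIGHT,
) -> np.ndarray:
    landmarks = set(layout.epicondyles) | set(layout.malleoli)
    return np.array([landmark_weight if l in landmarks else 1.0 for l in labels])


def _check_observability(model: Model, labels: list[str]) -> None:
    per_seg: dict[str, int] = {}
    for l in labels:
        per_seg[model.marker_segment(l)] = per_seg.get(model.marker_segment(l), 0) + 1
    thin = [s for s in ("pelvis", "thigh", "shank", "calcaneus") if per_seg.get(s, 0) < 3]
    if thin:
        warnings.warn(
            f"segments with fewer than 3 markers (pose weakly observable): {thin}",
            stacklevel=3,
        )


def _wrap_pi(x: float) -> float:
    return (x + np.pi) % (2 * np.pi) - np.pi


def canonicalize_coordinates(model: Model, q: np.ndarray) -> np.ndarray:
    """Map rotational coordinates onto the canonical branch.

    Euler-style sequences admit equivalent solutions (angle wraps and the
    dual branch); the forward map cannot distinguish them, but floating-axis
    moment extraction can.  For every joint the composed rotation is rebuilt
    and re-decomposed with the middle angle in [-pi/2, pi/2] and the outer
    angles wrapped to (-pi, pi], leaving the kinematics bitwise equivalent.
    """
    q = np.asarray(q, dtype=float).copy()
    offset = 0
    for joint in model.joints:
        rot_idx = [offset + k for k, c in enumerate(joint.coordinates) if c.kind == "rot"]
        rot_coords = [c for c in joint.coordinates if c.kind == "rot"]
        zxy = len(rot_idx) == 3 and all(
            abs(c.axis[j]) == 1.0 for c, j in zip(rot_coords, (2, 0, 1))
        )
        if zxy:
            Q = np.eye(3)
            for i, c in zip(rot_idx, rot_coords):
                Q = Q @ rotation_about(c.axis, q[i])
            # signed Z-X-Y sequence: axis = s * e_axis with s = +/-1
            s = [c.axis[j] for c, j in zip(rot_coords, (2, 0, 1))]
            ax = np.arcsin(np.clip(Q[2, 1], -1.0, 1.0))
            az = np.arctan2(-Q[0, 1], Q[1, 1])
            ay = np.arctan2(-Q[2, 0], Q[2, 2])
            for i, sign, val in zip(rot_idx, s, (az, ax, ay)):
                q[i] = val / sign
        else:
            for i in rot_idx:
                q[i] = _wrap_pi(q[i])
        offset += len(joint.coordinates)
    return q


def solve_ik_frame(
    model: Model,
    labels: list[str],
    observed: np.ndarray,
    weights: np.ndarray | None = None,
    q_init: np.ndarray | None = None,
    check_observability: bool = True,
) -> tuple[np.ndarray, float, bool]:
    """Solve one frame; returns ``(q, fit_rms, converged)``."""
    n = model.n_coordinates
    obs = np.asarray(observed, dtype=float).reshape(-1, 3)
    if len(labels) != len(obs):
        raise ValidationError("labels/observed mismatch")
    if weights is None:
        w = np.ones(len(labels))
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
    if check_observability:
        _check_observability(model, labels)
    q = np.zeros(n) if q_init is None else np.asarray(q_init, dtype=float).copy()

    sw = np.sqrt(np.repeat(w, 3))
    lam = 1e-6

    def residual(qv):
        state = propagate(model, qv)
        J, pos = marker_jacobian(model, state, labels)
        r = (obs - pos).reshape(-1)
        return r, J.reshape(-1, n)

    r, J = residual(q)
    obj = float(np.sum((sw * r) ** 2))
    converged = False
    eye = np.eye(n)
    for _ in range(MAX_ITER):
        Jw = J * sw[:, None]
        A = Jw.T @ Jw
        g = Jw.T @ (sw * r)
        step = np.linalg.solve(A + lam * eye, g)
        if np.linalg.norm(step) < STEP_TOL:
            converged = True
            break
        q_new = q + step
        r_new, J_new = residual(q_new)
        obj_new = float(np.sum((sw * r_new) ** 2))
        if obj_new <= obj * (1.0 + 1e-12) + 1e-18:
            accepted_change = obj - obj_new
            q, r, J, obj = q_new, r_new, J_new, obj_new
            lam = max(lam / 3.0, 1e-12)
            if accepted_change < OBJ_TOL:
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e8:
                break
    wsum = w.sum()
    rms = float(np.sqrt(np.sum(w * (r.reshape(-1, 3) ** 2).sum(axis=1)) / wsum))
    return canonicalize_coordinates(model, q), rms, converged


def solve_ik_trial(
    model: Model,
    trial: MarkerTrajectorySet,
    weights: np.ndarray | None = None,
    labels: list[str] | None = None,
    q_init: np.ndarray | None = None,
    filter_spec: FilterSpec | None = FilterSpec(),
    layout: MarkerLayout = DEFAULT_LAYOUT,
) -> CoordinateTrajectory:
    """Solve a whole trial with warm starting and compute derivatives.

    Coordinates are optionally filtered (zero-lag Butterworth by default)
    before central-difference differentiation; endpoints use one-sided
    differences.  Pass ``filter_spec=None`` to differentiate raw coordinates.
    """
    if labels is None:
        labels = [l for l in trial.labels if l in model.marker_labels()]
    if weights is None:
        weights = default_marker_weights(labels, layout)
    idx = trial.indices(labels)
    nf = trial.n_frames
    q = np.zeros((nf, model.n_coordinates))
    rms = np.zeros(nf)
    flags = np.zeros(nf, dtype=bool)
    q_prev = q_init
    _check_observability(model, labels)
    for f in range(nf):
        vis = ~trial.occluded[f, idx]
        lab_f = [l for l, v in zip(labels, vis) if v]
        obs_f = trial.positions[f, idx][vis]
        w_f = np.asarray(weights)[vis]
        qf, rf, ok = solve_ik_frame(
            model, lab_f, obs_f, w_f, q_prev, check_observability=False
        )
        q[f], rms[f], flags[f] = qf, rf, not ok
        q_prev = qf

    q_f = q if filter_spec is None else filter_spec.apply(q, trial.rate)
    qdot = differentiate(q_f, trial.rate, "central")
    qddot = differentiate(qdot, trial.rate, "central")
    return CoordinateTrajectory(
        list(model.coordinate_names), trial.times.copy(), q_f, qdot, qddot, rms, flags
    )
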