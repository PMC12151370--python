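"""Forward kinematics of the joint-frame chain.

One pass through the tree produces, for every segment, its lab pose together
with angular velocity/acceleration and the linear velocity/acceleration of
its origin and center of mass — and, for every generalized coordinate, its
instantaneous world axis and a point on that axis.  Those per-coordinate
records give the analytic marker Jacobian (used by the IK solver) and the
generalized-force projections (used by inverse dynamics) for free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import Model
from .rigid import RigidTransform, rotation_about

__all__ = ["SegmentState", "CoordInfo", "KinematicState", "propagate", "forward_markers", "marker_jacobian"]


@dataclass
class SegmentState:
    R: np.ndarray  # lab <- segment rotation
    p: np.ndarray  # origin (m)
    w: np.ndarray  # angular velocity (rad/s)
    alpha: np.ndarray  # angular acceleration (rad/s^2)
    v: np.ndarray  # origin velocity (m/s)
    a: np.ndarray  # origin acceleration (m/s^2)
    com: np.ndarray
    v_com: np.ndarray
    a_com: np.ndarray

    @property
    def pose(self) -> RigidTransform:
        return RigidTransform(self.R, self.p)


@dataclass
class CoordInfo:
    name: str
    joint: str
    kind: str  # "rot" | "trans"
    axis_w: np.ndarray  # world axis direction
    point_w: np.ndarray  # point on the axis (frame origin at this stage)
    # world-direction of the coupled-translation derivative dc/dq, if any
    coupling_dir_w: np.ndarray | None = None


@dataclass
class KinematicState:
    segments: dict  # name -> SegmentState
    coords: list  # CoordInfo per generalized coordinate
    q: np.ndarray
    qdot: np.ndarray
    qddot: np.ndarray



def _cr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3-vector cross product without numpy's generic-ufunc overhead."""
    return np.array(
        (
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        )
    )

class _Frame:
    __slots__ = ("R", "o", "w", "al", "v", "a")

    def __init__(self, R, o, w, al, v, a):
        self.R, self.o, self.w, self.al, self.v, self.a = R, o, w, al, v, a

    def shifted(self, r_local: np.ndarray, R_local: np.ndarray | None = None) -> "_Frame":
        """Move to a frame rigidly attached to this one (fixed transform)."""
        r = self.R @ r_local
        o = self.o + r
        v = self.v + _cr(self.w, r)
        a = self.a + np.cross(self.al, r) + np.cross(self.w, _cr(self.w, r))
        R = self.R if R_local is None else self.R @ R_local
        return _Frame(R, o, self.w, self.al, v, a)


def _interp_coupling(coupling, q1: float):
    angles, offsets = coupling
    angles = np.asarray(angles, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    x = np.clip(q1, angles[0], angles[-1])
    i = int(np.clip(np.searchsorted(angles, x) - 1, 0, len(angles) - 2))
    t = (x - angles[i]) / (angles[i + 1] - angles[i])
    c = offsets[i] + t * (offsets[i + 1] - offsets[i])
    dc = (offsets[i + 1] - offsets[i]) / (angles[i + 1] - angles[i])
    if q1 < angles[0] or q1 > angles[-1]:
        dc = np.zeros(3)
    return c, dc


def propagate(
    model: Model,
    q: np.ndarray,
    qdot: np.ndarray | None = None,
    qddot: np.ndarray | None = None,
) -> KinematicState:
    """Outward kinematics pass over the whole tree."""
    n = model.n_coordinates
    q = np.asarray(q, dtype=float).reshape(n)
    qd = np.zeros(n) if qdot is None else np.asarray(qdot, dtype=float).reshape(n)
    qdd = np.zeros(n) if qddot is None else np.asarray(qddot, dtype=float).reshape(n)

    frames: dict[str, _Frame] = {
        "ground": _Frame(np.eye(3), np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
    }
    segs: dict[str, SegmentState] = {}
    coords: list[CoordInfo] = []
    idx = 0
    for joint in model.joints:
        fr = frames[joint.parent]
        # fixed parent placement
        fr = fr.shifted(joint.parent_placement.translation, joint.parent_placement.rotation)
        # optional flexion-coupled translation (value driven by the joint's
        # first coordinate, directions fixed in the parent joint frame)
        coupling_dir_w = None
        if joint.coupling is not None:
            q1 = q[idx]
            c, dc = _interp_coupling(joint.coupling, q1)
            r = fr.R @ c
            d = fr.R @ dc
            coupling_dir_w = d
            o = fr.o + r
            v = (
                fr.v
                + _cr(fr.w, r)
                + d * qd[idx]
            )
            a = (
                fr.a
                + _cr(fr.al, r)
                + np.cross(fr.w, _cr(fr.w, r))
                + 2.0 * _cr(fr.w, d * qd[idx])
                + d * qdd[idx]
            )
            fr = _Frame(fr.R, o, fr.w, fr.al, v, a)
        for k, c in enumerate(joint.coordinates):
            n_w = fr.R @ c.axis
            info = CoordInfo(c.name, joint.name, c.kind, n_w, fr.o.copy())
            if k == 0 and coupling_dir_w is not None:
                info.coupling_dir_w = coupling_dir_w
            coords.append(info)
            if c.kind == "rot":
                R = fr.R @ rotation_about(c.axis, q[idx])
                w = fr.w + qd[idx] * n_w
                al = fr.al + qdd[idx] * n_w + _cr(fr.w, qd[idx] * n_w)
                fr = _Frame(R, fr.o, w, al, fr.v, fr.a)
            else:
                r = q[idx] * n_w
                o = fr.o + r
                v = fr.v + _cr(fr.w, r) + qd[idx] * n_w
                a = (
                    fr.a
                    + _cr(fr.al, r)
                    + np.cross(fr.w, _cr(fr.w, r))
                    + 2.0 * _cr(fr.w, qd[idx] * n_w)
                    + qdd[idx] * n_w
                )
                fr = _Frame(fr.R, o, fr.w, fr.al, v, a)
            idx += 1
        # inverse child placement (inlined to avoid transform allocation)
        Rc = joint.child_placement.rotation
        fr = fr.shifted(-(Rc.T @ joint.child_placement.translation), Rc.T)
        frames[joint.child] = fr
        seg = model.segments[joint.child]
        r_com = fr.R @ seg.com
        segs[joint.child] = SegmentState(
            R=fr.R,
            p=fr.o,
            w=fr.w,
            alpha=fr.al,
            v=fr.v,
            a=fr.a,
            com=fr.o + r_com,
            v_com=fr.v + _cr(fr.w, r_com),
            a_com=fr.a
            + _cr(fr.al, r_com)
            + _cr(fr.w, _cr(fr.w, r_com)),
        )
    return KinematicState(segs, coords, q, qd, qdd)


def batch_segment_poses(model: Model, q_series: np.ndarray) -> dict:
    """Vectorized position-level forward kinematics over a whole trial.

    Returns ``{segment: (R (F,3,3), p (F,3))}``.  Velocity-level quantities
    are not computed; use :func:`propagate` per frame for those.
    """
    q_series = np.asarray(q_series, dtype=float)
    nf = len(q_series)
    eye = np.broadcast_to(np.eye(3), (nf, 3, 3))
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "ground": (np.array(eye), np.zeros((nf, 3)))
    }
    idx = 0
    for joint in model.joints:
        R, o = poses[joint.parent]
        R = R.copy()
        o = o.copy()

        def shift(R, o, t, Rf=None):
            o = o + np.einsum("fij,j->fi", R, t)
            if Rf is not None:
                R = np.einsum("fij,jk->fik", R, Rf)
            return R, o

        R, o = shift(R, o, joint.parent_placement.translation, joint.parent_placement.rotation)
        if joint.coupling is not None:
            c = np.array([_interp_coupling(joint.coupling, qv)[0] for qv in q_series[:, idx]])
            o = o + np.einsum("fij,fj->fi", R, c)
        for c in joint.coordinates:
            th = q_series[:, idx]
            if c.kind == "rot":
                n = c.axis
                K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
                Rrot = (
                    np.eye(3)[None, :, :]
                    + np.sin(th)[:, None, None] * K
                    + (1 - np.cos(th))[:, None, None] * (K @ K)
                )
                R = np.einsum("fij,fjk->fik", R, Rrot)
            else:
                o = o + th[:, None] * np.einsum("fij,j->fi", R, c.axis)
            idx += 1
        Rc = joint.child_placement.rotation
        R, o = shift(R, o, -(Rc.T @ joint.child_placement.translation), Rc.T)
        poses[joint.child] = (R, o)
    del poses["ground"]
    return poses


def forward_markers(
    model: Model, q: np.ndarray, labels: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Lab positions of model markers at configuration ``q``."""
    state = propagate(model, q)
    if labels is None:
        labels = model.marker_labels()
    out = np.empty((len(labels), 3))
    for i, lbl in enumerate(labels):
        seg_name = model.marker_segment(lbl)
        st = state.segments[seg_name]
        out[i] = st.p + st.R @ model.segments[seg_name].local_markers[lbl]
    return labels, out


def marker_jacobian(
    model: Model, state: KinematicState, labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobian d(marker)/dq, shape (m, 3, n), plus marker positions."""
    n = model.n_coordinates
    m = len(labels)
    J = np.zeros((m, 3, n))
    pos = np.empty((m, 3))
    by_segment: dict[str, list[int]] = {}
    for i, lbl in enumerate(labels):
        seg_name = model.marker_segment(lbl)
        st = state.segments[seg_name]
        pos[i] = st.p + st.R @ model.segments[seg_name].local_markers[lbl]
        by_segment.setdefault(seg_name, []).append(i)
    for seg_name, rows in by_segment.items():
        path = model.path_coords[seg_name]
        infos = [state.coords[ci] for ci in path]
        axes = np.array([info.axis_w for info in infos])  # (k, 3)
        points = np.array([info.point_w for info in infos])
        is_rot = np.array([info.kind == "rot" for info in infos])
        p = pos[rows]  # (mr, 3)
        lever = p[:, None, :] - points[None, :, :]  # (mr, k, 3)
        block = np.cross(axes[None, :, :], lever)  # rotational columns
        block[:, ~is_rot, :] = axes[~is_rot]
        for ki, info in enumerate(infos):
            if info.coupling_dir_w is not None:
                block[:, ki, :] += info.coupling_dir_w
        J[np.ix_(rows, [0, 1, 2], path)] = np.transpose(block, (0, 2, 1))
    return J, pos
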