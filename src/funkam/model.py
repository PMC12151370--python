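"""Generic 7-segment / 18-DOF unilateral lower-extremity model.

Segments form a tree rooted at ground -> pelvis.  A joint couples a parent and
a child segment through two fixed *joint frame placements* (one in each
segment) and an ordered list of 1-DOF coordinates acting inside the joint
frame::

    X_lab_child = X_lab_parent @ P @ Q(q) @ inv(C)

where ``P``/``C`` are the parent/child placements and ``Q(q)`` composes the
coordinate rotations/translations.  In the generic model the knee and ankle
joint frames carry the joint-coordinate-system orientation (x posterior,
y distal, z lateral); the functional-axis integration strategies only
*reorient* these placements, never translate them.

Three subject-specific variants are built here:

* ``scale_model``        -- conventional scaling (CON): segment lengths from the
  functional joint centers, generic joint-frame orientations.
* ``integrate_far_fun1`` -- iterative proximal-frame integration (FUN 1):
  re-orient only the proximal (femur-side knee, tibia-side ankle) frames.
* ``integrate_far_fun2`` -- both-frame integration (FUN 2): reorient proximal
  and distal frames, leaving the default relative segment orientation alone.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from . import anthropometry as anth
from .anthropometry import DEFAULT_LAYOUT, GRAVITY, MarkerLayout
from .calibration import FunctionalCalibration
from .errors import ValidationError
from .markers import MarkerTrajectorySet
from .rigid import RigidTransform, estimate_pose

__all__ = [
    "Anthropometry",
    "Segment",
    "Coordinate",
    "Joint",
    "Model",
    "make_generic_model",
    "scale_model",
    "integrate_far_fun1",
    "integrate_far_fun2",
    "static_segment_poses",
]


@dataclass(frozen=True)
class Anthropometry:
    """Subject body mass (kg) and height (m)."""

    mass: float
    height: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise ValidationError("mass and height must be positive")


@dataclass
class Segment:
    name: str
    mass: float
    com: np.ndarray
    inertia: np.ndarray  # about the com, in the segment frame
    local_markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass < 0:
            raise ValidationError("segment mass must be nonnegative")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ValidationError("inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) < -1e-12):
            raise ValidationError("inertia must be positive semidefinite")
        self.local_markers = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.local_markers.items()
        }


@dataclass
class Coordinate:
    name: str
    kind: str  # "rot" | "trans"
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValidationError(f"coordinate {self.name}: axis must be unit length")
        if self.kind not in ("rot", "trans"):
            raise ValidationError(f"coordinate {self.name}: unknown kind {self.kind!r}")


@dataclass
class Joint:
    name: str
    parent: str
    child: str
    parent_placement: RigidTransform
    child_placement: RigidTransform
    coordinates: list
    # optional flexion-coupled tibiofemoral translation: (angles_rad, offsets (n,3))
    coupling: tuple | None = None

    def __post_init__(self) -> None:
        self.parent_placement.validate(1e-8)
        self.child_placement.validate(1e-8)


class Model:
    """Segment tree + joints + gravity, with a coordinate index map."""

    def __init__(self, segments: dict, joints: list, gravity: np.ndarray = GRAVITY):
        self.segments: dict[str, Segment] = segments
        self.joints: list[Joint] = joints
        self.gravity = np.asarray(gravity, dtype=float).reshape(3)
        self._index()
        self.validate()

    def _index(self) -> None:
        self.joint_by_name = {j.name: j for j in self.joints}
        self.joint_of_child = {j.child: j for j in self.joints}
        self.coordinate_names: list[str] = []
        self.coord_joint: list[tuple[Joint, int]] = []
        for j in self.joints:
            for k, c in enumerate(j.coordinates):
                self.coordinate_names.append(c.name)
                self.coord_joint.append((j, k))
        self.coord_index = {n: i for i, n in enumerate(self.coordinate_names)}
        # topological order of segments (joints are required to be in order)
        self.segment_order = [j.child for j in self.joints]
        # coordinate indices on the path from ground to each segment
        self.path_coords: dict[str, list[int]] = {}
        offset = 0
        joint_coord_range = {}
        for j in self.joints:
            joint_coord_range[j.name] = list(range(offset, offset + len(j.coordinates)))
            offset += len(j.coordinates)
        for j in self.joints:
            parent_path = self.path_coords.get(j.parent, [])
            self.path_coords[j.child] = parent_path + joint_coord_range[j.name]
        # children map for subtree queries
        self.children: dict[str, list[str]] = {name: [] for name in self.segments}
        for j in self.joints:
            if j.parent != "ground":
                self.children[j.parent].append(j.child)

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinate_names)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def validate(self) -> None:
        roots = [j for j in self.joints if j.parent == "ground"]
        if len(roots) != 1:
            raise ValidationError("model must have exactly one root joint")
        seen = {"ground"}
        for j in self.joints:
            if j.parent not in seen:
                raise ValidationError(f"joint {j.name}: parent {j.parent} not yet defined")
            if j.child in seen:
                raise ValidationError(f"joint {j.name}: duplicate child {j.child}")
            if j.child not in self.segments:
                raise ValidationError(f"joint {j.name}: unknown child segment")
            seen.add(j.child)
        if set(self.segments) != seen - {"ground"}:
            raise ValidationError("segments and joint tree are inconsistent")

    def subtree(self, segment: str) -> list[str]:
        out = [segment]
        stack = list(self.children[segment])
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(self.children[s])
        return out

    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    def marker_segment(self, label: str) -> str:
        for s in self.segments.values():
            if label in s.local_markers:
                return s.name
        raise ValidationError(f"model has no marker {label!r}")

    def marker_labels(self) -> list[str]:
        out = []
        for name in self.segment_order:
            out.extend(self.segments[name].local_markers)
        return out

    def copy(self) -> "Model":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# generic model
# ---------------------------------------------------------------------------


def make_generic_model(knee_translation_table: tuple | None = None) -> Model:
    """Build the generic 7-segment / 18-DOF model from the parameter tables.

    ``knee_translation_table`` optionally enables the flexion-coupled
    tibiofemoral translation (piecewise-linear ``(flexion_rad, offsets)``
    lookup in the femur-side knee frame); it is off by default because the
    frontal-plane moment is governed by axis orientation, not by the small
    sagittal gliding translation.
    """
    segments = {}
    for name, (frac, com, gyr) in anth.SEGMENT_TABLE.items():
        mass = frac * anth.GENERIC_MASS
        inertia = np.diag(mass * np.asarray(gyr, dtype=float) ** 2)
        markers = {
            lbl: np.asarray(pos, dtype=float)
            for lbl, (seg, pos) in anth.MARKER_TABLE.items()
            if seg == name
        }
        segments[name] = Segment(name, mass, np.asarray(com), inertia, markers)

    joints = []
    for jname, (parent, child, pt, ct, R) in anth.JOINT_GEOMETRY.items():
        coords = [
            Coordinate(cname, kind, np.asarray(axis))
            for cname, kind, axis in anth.JOINT_COORDINATES[jname]
        ]
        coupling = knee_translation_table if jname == "knee" else None
        joints.append(
            Joint(
                jname,
                parent,
                child,
                RigidTransform(np.asarray(R, dtype=float), np.asarray(pt, dtype=float)),
                RigidTransform(np.asarray(R, dtype=float), np.asarray(ct, dtype=float)),
                coords,
                coupling,
            )
        )
    return Model(segments, joints)


# ---------------------------------------------------------------------------
# scaling (CON)
# ---------------------------------------------------------------------------

_GENERIC_PELVIS_SPAN = float(
    np.linalg.norm(
        np.asarray(anth.MARKER_TABLE["RASI"][1]) - np.asarray(anth.MARKER_TABLE["LASI"][1])
    )
)
_GENERIC_FOOT_SPAN = float(
    np.linalg.norm(
        np.asarray(anth.MARKER_TABLE["HEEL"][1]) - np.asarray(anth.MARKER_TABLE["MT2"][1])
    )
)


def _static_positions(static_markers: MarkerTrajectorySet, frame: int = 0):
    def pos(label: str) -> np.ndarray:
        return static_markers.positions[frame, static_markers.index(label)]

    return pos


def scale_factors(
    hjc: np.ndarray,
    kjc: np.ndarray,
    ajc: np.ndarray,
    static_markers: MarkerTrajectorySet,
) -> dict:
    """Per-segment isotropic scale factors from joint-center spacings.

    Thigh: HJC-KJC; shank: KJC-AJC; pelvis: inter-ASIS span; foot segments:
    heel to metatarsal-II span; torso follows the pelvis.
    """
    pos = _static_positions(static_markers)
    s_thigh = float(np.linalg.norm(np.asarray(hjc) - np.asarray(kjc))) / anth.THIGH_LENGTH
    s_shank = float(np.linalg.norm(np.asarray(kjc) - np.asarray(ajc))) / anth.SHANK_LENGTH
    s_pelvis = float(np.linalg.norm(pos("RASI") - pos("LASI"))) / _GENERIC_PELVIS_SPAN
    s_foot = float(np.linalg.norm(pos("HEEL") - pos("MT2"))) / _GENERIC_FOOT_SPAN
    return {
        "pelvis": s_pelvis,
        "torso": s_pelvis,
        "thigh": s_thigh,
        "shank": s_shank,
        "talus": s_foot,
        "calcaneus": s_foot,
        "toes": s_foot,
    }


def apply_scaling(generic: Model, factors: dict, anthro: Anthropometry) -> Model:
    """Scale lengths/markers/com linearly, masses to the subject with generic
    fractions, inertia by mass x length^2."""
    model = generic.copy()
    for name, seg in model.segments.items():
        s = factors[name]
        frac = anth.SEGMENT_TABLE[name][0]
        new_mass = frac * anthro.mass
        mass_ratio = new_mass / seg.mass if seg.mass > 0 else 0.0
        seg.com = seg.com * s
        seg.inertia = seg.inertia * mass_ratio * s**2
        seg.mass = new_mass
        seg.local_markers = {k: v * s for k, v in seg.local_markers.items()}
    for j in model.joints:
        sp = factors.get(j.parent, 1.0)
        sc = factors[j.child]
        j.parent_placement = RigidTransform(
            j.parent_placement.rotation, j.parent_placement.translation * sp
        )
        j.child_placement = RigidTransform(
            j.child_placement.rotation, j.child_placement.translation * sc
        )
    return model


def static_segment_poses(
    model: Model,
    static_markers: MarkerTrajectorySet,
    layout: MarkerLayout = DEFAULT_LAYOUT,
    frame: int = 0,
) -> dict:
    """Best-fit lab pose of each segment in the static reference.

    Segments with >= 3 markers are posed by SVD fit of their model markers to
    the observed static markers.  The markerless talus and the single-marker
    toes are placed through the joint chain at zero joint angles relative to
    their fitted neighbours.
    """
    poses: dict[str, RigidTransform] = {}
    fit_groups = {
        "pelvis": list(layout.pelvis_markers),
        "thigh": list(layout.thigh_cluster) + list(layout.epicondyles),
        "shank": list(layout.shank_cluster) + list(layout.malleoli),
        "calcaneus": list(layout.foot_carrier),
        "torso": list(layout.torso_markers),
    }
    for seg_name, labels in fit_groups.items():
        seg = model.segments[seg_name]
        usable = [
            l
            for l in labels
            if l in seg.local_markers
            and l in static_markers.labels
            and not static_markers.occluded[frame, static_markers.index(l)]
        ]
        local = np.array([seg.local_markers[l] for l in usable])
        obs = np.array(
            [static_markers.positions[frame, static_markers.index(l)] for l in usable]
        )
        T, _ = estimate_pose(local, obs)
        poses[seg_name] = T

    ankle = model.joint_by_name["ankle"]
    subtalar = model.joint_by_name["subtalar"]
    mtp = model.joint_by_name["mtp"]
    # talus from the shank at zero ankle angle
    poses["talus"] = (
        poses["shank"].compose(ankle.parent_placement).compose(ankle.child_placement.invert())
    )
    poses["toes"] = (
        poses["calcaneus"].compose(mtp.parent_placement).compose(mtp.child_placement.invert())
    )
    # keep the talus consistent with the fitted calcaneus as well (zero subtalar)
    poses["talus_from_foot"] = (
        poses["calcaneus"]
        .compose(subtalar.child_placement)
        .compose(subtalar.parent_placement.invert())
    )
    return poses


def adjust_markers_to_static(
    model: Model,
    static_markers: MarkerTrajectorySet,
    layout: MarkerLayout = DEFAULT_LAYOUT,
    frame: int = 0,
) -> Model:
    """Re-seat model markers so the static reference is reproduced exactly."""
    model = model.copy()
    poses = static_segment_poses(model, static_markers, layout, frame)
    for seg_name in ("pelvis", "thigh", "shank", "calcaneus", "toes", "torso"):
        seg = model.segments[seg_name]
        T_inv = poses[seg_name].invert()
        for lbl in list(seg.local_markers):
            if lbl in static_markers.labels and not static_markers.occluded[
                frame, static_markers.index(lbl)
            ]:
                obs = static_markers.positions[frame, static_markers.index(lbl)]
                seg.local_markers[lbl] = T_inv.apply(obs)
    return model


def scale_model(
    generic: Model,
    hjc: np.ndarray,
    kjc: np.ndarray,
    ajc: np.ndarray,
    static_markers: MarkerTrajectorySet,
    anthro: Anthropometry,
    layout: MarkerLayout = DEFAULT_LAYOUT,
) -> Model:
    """Conventionally scaled model (CON).

    Segment lengths come from the functional joint-center spacings, masses
    preserve the subject's total mass with generic fractions, inertias scale
    by mass x length^2, and the model markers are adjusted to match the
    static reference.  Joint-frame orientations stay generic.
    """
    factors = scale_factors(hjc, kjc, ajc, static_markers)
    model = apply_scaling(generic, factors, anthro)
    return adjust_markers_to_static(model, static_markers, layout)


# ---------------------------------------------------------------------------
# functional-axis integration
# ---------------------------------------------------------------------------


def _reorient(joint: Joint, which: str, new_axes_in_segment: np.ndarray) -> None:
    if which == "parent":
        joint.parent_placement = RigidTransform(
            new_axes_in_segment, joint.parent_placement.translation
        )
    else:
        joint.child_placement = RigidTransform(
            new_axes_in_segment, joint.child_placement.translation
        )


def integrate_far_fun1(
    generic: Model,
    cal: FunctionalCalibration,
    static_markers: MarkerTrajectorySet,
    anthro: Anthropometry,
    layout: MarkerLayout = DEFAULT_LAYOUT,
) -> Model:
    """Iterative proximal-frame functional-axis integration (FUN 1).

    Proceeding proximal to distal, each segment is scaled with its own
    markers and only the *proximal* joint frame of the knee (femur side) and
    ankle (tibia side) is reoriented to the functional JCS, expressed in the
    segment through its cluster markers.  Distal joint frames keep the
    generic orientation.  Because the scaler derives each segment's factor
    from its own joint-center spacing/markers, the iterative ordering reduces
    to per-segment scaling here.
    """
    model = scale_model(generic, cal.hjc, cal.kjc, cal.ajc, static_markers, anthro, layout)
    poses = static_segment_poses(model, static_markers, layout)
    knee = model.joint_by_name["knee"]
    ankle = model.joint_by_name["ankle"]
    _reorient(knee, "parent", poses["thigh"].rotation.T @ cal.jcs_knee.axes)
    _reorient(ankle, "parent", poses["shank"].rotation.T @ cal.jcs_ankle.axes)
    model._index()
    return model


def integrate_far_fun2(
    scaled: Model,
    cal: FunctionalCalibration,
    static_markers: MarkerTrajectorySet,
    layout: MarkerLayout = DEFAULT_LAYOUT,
) -> Model:
    """Both-frame functional-axis integration (FUN 2).

    Starting from the scaled CON model, both knee joint frames (femur and
    tibia side) and both ankle joint frames (tibia and talus side) are
    reoriented to the corresponding functional JCS expressed in each segment
    via its cluster/foot markers.  Placement translations, segment default
    orientations and markers are untouched.
    """
    model = scaled.copy()
    poses = static_segment_poses(model, static_markers, layout)
    knee = model.joint_by_name["knee"]
    ankle = model.joint_by_name["ankle"]
    _reorient(knee, "parent", poses["thigh"].rotation.T @ cal.jcs_knee.axes)
    _reorient(knee, "child", poses["shank"].rotation.T @ cal.jcs_knee.axes)
    _reorient(ankle, "parent", poses["shank"].rotation.T @ cal.jcs_ankle.axes)
    _reorient(ankle, "child", poses["talus_from_foot"].rotation.T @ cal.jcs_ankle.axes)
    model._index()
    return model
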