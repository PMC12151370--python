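"""Generic model parameter table and marker layout.

The generic subject is 1.74 m / 64 kg.  Segment lengths follow standard
stature fractions, masses are fractions of total body mass, and inertias are
diagonal with documented radii of gyration.  Because the model is a
*unilateral* 7-segment chain, the contralateral leg, arms and head are lumped
into the torso segment so that the model's total mass equals the subject's
body mass.  All values here are declared package constants (they parameterize
the generic model; they are not fitted to any dataset).

Frames: lab/ground is X anterior, Y up, Z to the subject's right.  Every
segment frame is aligned with the lab frame in the neutral standing pose.
Segment origins sit at the proximal joint center (thigh at HJC, shank at KJC,
talus at AJC).  Knee and ankle joint frames use the joint-coordinate-system
orientation produced by the functional construction (x posterior, y distal,
z medial-to-lateral for the right side), i.e. a 180° z-rotation relative to
the segment frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GENERIC_HEIGHT = 1.74  # m
GENERIC_MASS = 64.0  # kg
GRAVITY = np.array([0.0, -9.81, 0.0])  # m/s^2

THIGH_LENGTH = 0.245 * GENERIC_HEIGHT  # HJC -> KJC
SHANK_LENGTH = 0.246 * GENERIC_HEIGHT  # KJC -> AJC

# JCS orientation of knee/ankle joint frames relative to their segment frames
# in the neutral pose (x posterior, y distal, z lateral).
JCS_R = np.diag([-1.0, -1.0, 1.0])

# name -> (mass fraction, com in segment frame [m], radii of gyration [m])
SEGMENT_TABLE: dict[str, tuple[float, tuple, tuple]] = {
    "pelvis": (0.142, (-0.02, 0.03, 0.0), (0.10, 0.10, 0.10)),
    # trunk + head + arms + contralateral leg lumped (unilateral model)
    "torso": (0.6945, (0.0, 0.20, 0.0), (0.25, 0.30, 0.25)),
    "thigh": (0.100, (0.0, -0.433 * THIGH_LENGTH, 0.0),
              (0.329 * THIGH_LENGTH, 0.149 * THIGH_LENGTH, 0.329 * THIGH_LENGTH)),
    "shank": (0.0465, (0.0, -0.433 * SHANK_LENGTH, 0.0),
              (0.255 * SHANK_LENGTH, 0.103 * SHANK_LENGTH, 0.249 * SHANK_LENGTH)),
    "talus": (0.0015, (0.0, 0.0, 0.0), (0.01, 0.01, 0.01)),
    "calcaneus": (0.0125, (0.06, -0.02, 0.0), (0.05, 0.05, 0.05)),
    "toes": (0.003, (0.03, -0.005, 0.0), (0.02, 0.02, 0.02)),
}

# joint name -> (parent, child, parent-placement translation, child translation,
#                placement rotation for both frames)
JOINT_GEOMETRY: dict[str, tuple] = {
    "ground": ("ground", "pelvis", (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), np.eye(3)),
    "back": ("pelvis", "torso", (-0.03, 0.10, 0.0), (0.0, 0.0, 0.0), np.eye(3)),
    "hip": ("pelvis", "thigh", (0.0, -0.05, 0.084), (0.0, 0.0, 0.0), np.eye(3)),
    "knee": ("thigh", "shank", (0.0, -THIGH_LENGTH, 0.0), (0.0, 0.0, 0.0), JCS_R),
    "ankle": ("shank", "talus", (0.0, -SHANK_LENGTH, 0.0), (0.0, 0.0, 0.0), JCS_R),
    "subtalar": ("talus", "calcaneus", (0.0, -0.035, 0.0), (0.0, 0.0, 0.0), np.eye(3)),
    "mtp": ("calcaneus", "toes", (0.13, -0.04, 0.0), (0.0, 0.0, 0.0), np.eye(3)),
}

# joint name -> list of (coordinate name, kind, axis in joint frame)
# Signs: flexion, adduction, internal rotation, dorsiflexion, inversion and toe
# extension positive, right-side conventions.
JOINT_COORDINATES: dict[str, list[tuple[str, str, tuple]]] = {
    "ground": [
        ("pelvis_tx", "trans", (1.0, 0.0, 0.0)),
        ("pelvis_ty", "trans", (0.0, 1.0, 0.0)),
        ("pelvis_tz", "trans", (0.0, 0.0, 1.0)),
        ("pelvis_rot_z", "rot", (0.0, 0.0, 1.0)),
        ("pelvis_rot_x", "rot", (1.0, 0.0, 0.0)),
        ("pelvis_rot_y", "rot", (0.0, 1.0, 0.0)),
    ],
    "back": [
        ("lumbar_extension", "rot", (0.0, 0.0, 1.0)),
        ("lumbar_bending", "rot", (1.0, 0.0, 0.0)),
        ("lumbar_rotation", "rot", (0.0, 1.0, 0.0)),
    ],
    "hip": [
        ("hip_flexion", "rot", (0.0, 0.0, 1.0)),
        ("hip_adduction", "rot", (1.0, 0.0, 0.0)),
        ("hip_rotation", "rot", (0.0, 1.0, 0.0)),
    ],
    # knee joint frame is JCS-oriented; these axis signs keep flexion,
    # adduction and internal rotation anatomically positive.
    "knee": [
        ("knee_flexion", "rot", (0.0, 0.0, -1.0)),
        ("knee_adduction", "rot", (-1.0, 0.0, 0.0)),
        ("knee_rotation", "rot", (0.0, -1.0, 0.0)),
    ],
    "ankle": [("ankle_dorsiflexion", "rot", (0.0, 0.0, 1.0))],
    "subtalar": [("subtalar_inversion", "rot", (-1.0, 0.0, 0.0))],
    "mtp": [("mtp_extension", "rot", (0.0, 0.0, 1.0))],
}

# marker label -> (segment, local position [m]) for the generic subject
MARKER_TABLE: dict[str, tuple[str, tuple]] = {
    "RASI": ("pelvis", (0.085, 0.02, 0.115)),
    "LASI": ("pelvis", (0.085, 0.02, -0.115)),
    "RPSI": ("pelvis", (-0.115, 0.04, 0.045)),
    "LPSI": ("pelvis", (-0.115, 0.04, -0.045)),
    "RILC": ("pelvis", (0.01, 0.105, 0.13)),
    "LILC": ("pelvis", (0.01, 0.105, -0.13)),
    "THI1": ("thigh", (0.02, -0.16, 0.065)),
    "THI2": ("thigh", (0.055, -0.20, 0.055)),
    "THI3": ("thigh", (0.015, -0.25, 0.07)),
    "THI4": ("thigh", (0.05, -0.29, 0.06)),
    "KNEL": ("thigh", (0.0, -THIGH_LENGTH, 0.055)),
    "KNEM": ("thigh", (0.0, -THIGH_LENGTH, -0.055)),
    "SHA1": ("shank", (0.01, -0.13, 0.055)),
    "SHA2": ("shank", (0.045, -0.17, 0.05)),
    "SHA3": ("shank", (0.005, -0.22, 0.06)),
    "SHA4": ("shank", (0.04, -0.26, 0.05)),
    "ANKL": ("shank", (0.0, -SHANK_LENGTH, 0.045)),
    "ANKM": ("shank", (0.0, -SHANK_LENGTH, -0.045)),
    "CAPF": ("shank", (0.005, -0.06, 0.055)),
    "TTUB": ("shank", (0.04, -0.07, 0.0)),
    "HEEL": ("calcaneus", (-0.045, -0.01, 0.0)),
    "MT1": ("calcaneus", (0.105, -0.03, -0.04)),
    "MT5": ("calcaneus", (0.10, -0.03, 0.055)),
    "MT2": ("calcaneus", (0.125, -0.03, 0.01)),
    "TOE2": ("toes", (0.045, -0.02, 0.005)),
    "C7": ("torso", (-0.07, 0.42, 0.0)),
    "CLAV": ("torso", (0.05, 0.38, 0.0)),
    "STRN": ("torso", (0.06, 0.28, 0.0)),
}

# reference contact point of the foot sole on the plate, in the calcaneus frame
PLATE_CONTACT_LOCAL = np.array([0.09, -0.04, 0.005])


@dataclass(frozen=True)
class MarkerLayout:
    """Which markers play which role in calibration and tracking."""

    pelvis_markers: tuple = ("RASI", "LASI", "RPSI", "LPSI", "RILC", "LILC")
    pelvis_donors: tuple = ("RASI", "LASI", "RILC", "LILC")
    psis_markers: tuple = ("RPSI", "LPSI")
    thigh_cluster: tuple = ("THI1", "THI2", "THI3", "THI4")
    shank_cluster: tuple = ("SHA1", "SHA2", "SHA3", "SHA4")
    foot_carrier: tuple = ("HEEL", "MT1", "MT5", "MT2")
    epicondyles: tuple = ("KNEL", "KNEM")  # lateral, medial
    malleoli: tuple = ("ANKL", "ANKM")  # lateral, medial
    additional_hip: tuple = ("RILC", "LILC")
    additional_tibia: tuple = ("CAPF", "TTUB")
    additional_foot: tuple = ("MT2", "TOE2")
    torso_markers: tuple = ("C7", "CLAV", "STRN")
    segment_of: dict = field(
        default_factory=lambda: {k: v[0] for k, v in MARKER_TABLE.items()}
    )

    def required_for_calibration(self) -> list[str]:
        req = (
            list(self.pelvis_markers)
            + list(self.thigh_cluster)
            + list(self.shank_cluster)
            + list(self.foot_carrier)
            + list(self.epicondyles)
            + list(self.malleoli)
        )
        return req


DEFAULT_LAYOUT = MarkerLayout()
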