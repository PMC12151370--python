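"""SCoRE, SARA, joint coordinate systems and the full calibration."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import funkam as fk
from funkam.calibration import (
    build_ankle_jcs,
    build_knee_jcs,
    calibrate,
    project_midpoint_onto_axis,
    sara,
    score,
    transfer_to_trial,
)
from funkam.errors import (
    DegenerateAxisError,
    IllPosedAxisError,
    IllPosedCenterError,
    MissingMarkerError,
)
from funkam.rigid import RigidTransform, rotation_about


def ball_joint_poses(rng, center_parent, center_child, n=60, amplitude=0.7):
    """Two bodies sharing an exact ball joint at a common lab point."""
    poses_p, poses_c = [], []
    for f in range(n):
        Rp = Rotation.from_rotvec(0.2 * np.sin(0.1 * f) * np.array([0, 0, 1.0])).as_matrix()
        tp = np.array([0.0, 0.9, 0.0]) - Rp @ center_parent
        axis = np.array([np.cos(0.21 * f), np.sin(0.17 * f), np.sin(0.11 * f)])
        Rc = Rotation.from_rotvec(amplitude * np.sin(0.13 * f + 0.4) * axis / np.linalg.norm(axis)).as_matrix()
        tc = (Rp @ center_parent + tp) - Rc @ center_child
        poses_p.append(RigidTransform(Rp, tp))
        poses_c.append(RigidTransform(Rc, tc))
    return poses_p, poses_c


def hinge_poses(rng, point_p, dir_p, n=60, sweep=(0.1, 1.3)):
    """Child rotating about a fixed axis of the (static) parent."""
    dir_p = dir_p / np.linalg.norm(dir_p)
    poses_p = [RigidTransform(np.eye(3), np.zeros(3)) for _ in range(n)]
    poses_c = []
    for f in range(n):
        ang = sweep[0] + (sweep[1] - sweep[0]) * 0.5 * (1 - np.cos(2 * np.pi * f / n))
        R = rotation_about(dir_p, ang)
        t = point_p - R @ point_p
        poses_c.append(RigidTransform(R, t))
    return poses_p, poses_c


class TestScore:
    def test_exact_ball_joint_recovered(self, rng):
        cp = np.array([0.1, -0.2, 0.05])
        cc = np.array([-0.05, 0.3, 0.0])
        pp, pc = ball_joint_poses(rng, cp, cc)
        est_p, est_c, rms = score(pp, pc)
        assert np.linalg.norm(est_p - cp) < 1e-10
        assert np.linalg.norm(est_c - cc) < 1e-10
        assert rms < 1e-10

    def test_noisy_center_error_below_5mm(self, rng):
        """1 mm pose-level noise leaves the center within millimetres."""
        cp = np.array([0.1, -0.2, 0.05])
        cc = np.array([-0.05, 0.3, 0.0])
        errs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            pp, pc = ball_joint_poses(r, cp, cc, n=120)
            pc = [RigidTransform(T.rotation, T.translation + r.normal(scale=1e-3, size=3)) for T in pc]
            est_p, _, _ = score(pp, pc)
            errs.append(np.linalg.norm(est_p - cp))
        assert np.median(errs) < 5e-3

    def test_pure_hinge_raises(self, rng):
        pp, pc = hinge_poses(rng, np.array([0.1, 0.2, 0.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(IllPosedCenterError):
            score(pp, pc)

    def test_small_rotation_range_warns(self, rng):
        cp = np.array([0.1, -0.2, 0.05])
        cc = np.array([-0.05, 0.3, 0.0])
        pp, pc = ball_joint_poses(rng, cp, cc, amplitude=0.05)
        with pytest.warns(UserWarning, match="rotation"):
            score(pp, pc)

    def test_parent_child_symmetry(self, rng):
        cp = np.array([0.1, -0.2, 0.05])
        cc = np.array([-0.05, 0.3, 0.0])
        pp, pc = ball_joint_poses(rng, cp, cc)
        a_p, a_c, _ = score(pp, pc)
        b_c, b_p, _ = score(pc, pp)
        assert np.allclose(a_p, b_p, atol=1e-10)
        assert np.allclose(a_c, b_c, atol=1e-10)


class TestSara:
    def test_exact_hinge_axis_recovered(self, rng):
        point = np.array([0.07, -0.42, 0.01])
        direction = np.array([0.1, 0.05, 0.99])
        direction /= np.linalg.norm(direction)
        pp, pc = hinge_poses(rng, point, direction)
        res = sara(pp, pc)
        assert 1 - abs(np.dot(res.dir_parent, direction)) < 1e-10
        # recovered point lies on the true axis
        d = res.point_parent - point
        assert np.linalg.norm(d - np.dot(d, direction) * direction) < 1e-8

    def test_noisy_direction_error_below_one_degree(self):
        point = np.array([0.07, -0.42, 0.01])
        direction = np.array([0.0, 0.05, 1.0])
        direction /= np.linalg.norm(direction)
        errs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            pp, pc = hinge_poses(r, point, direction, n=120)
            pc = [RigidTransform(T.rotation, T.translation + r.normal(scale=1e-3, size=3)) for T in pc]
            res = sara(pp, pc)
            errs.append(np.degrees(np.arccos(np.clip(abs(np.dot(res.dir_parent, direction)), -1, 1))))
        assert np.median(errs) < 1.0

    def test_ball_joint_motion_raises(self, rng):
        pp, pc = ball_joint_poses(rng, np.array([0.1, 0.0, 0.0]), np.array([0.0, 0.2, 0.0]))
        with pytest.raises(IllPosedAxisError):
            sara(pp, pc)

    def test_null_direction_consistency(self, rng):
        """Parent and child axis halves map to the same lab direction."""
        point = np.array([0.0, -0.4, 0.0])
        direction = np.array([0.2, 0.0, 1.0])
        direction /= np.linalg.norm(direction)
        pp, pc = hinge_poses(rng, point, direction)
        res = sara(pp, pc)
        lab_p = pp[10].rotation @ res.dir_parent
        lab_c = pc[10].rotation @ res.dir_child
        assert np.linalg.norm(np.cross(lab_p, lab_c)) < 1e-8


class TestProjections:
    def test_midpoint_on_axis_is_fixed_point(self):
        p = project_midpoint_onto_axis([0, 0, 1.0], [0, 0, 3.0], [0, 0, 0.0], [0, 0, 1.0])
        assert np.allclose(p, [0, 0, 2.0])

    def test_hand_computed_projection(self):
        p = project_midpoint_onto_axis([1, 2, 3.0], [1, 2, 3.0], [0, 0, 0.0], [0, 0, 1.0])
        assert np.allclose(p, [0, 0, 3.0])

    def test_matches_line_search(self, rng):
        ap = rng.normal(size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        m1, m2 = rng.normal(size=3), rng.normal(size=3)
        proj = project_midpoint_onto_axis(m1, m2, ap, d)
        mid = (m1 + m2) / 2
        s = np.linspace(-10, 10, 400001)
        pts = ap[None] + s[:, None] * d[None]
        best = pts[np.argmin(np.linalg.norm(pts - mid, axis=1))]
        assert np.linalg.norm(proj - best) < 1e-4


class TestJcsConstruction:
    def test_stated_cross_product_example(self):
        jf = build_knee_jcs([0, 0, 0.0], [0, 1, 0.0], [0, 0, 1.0])
        assert np.allclose(jf.x_axis, [-1, 0, 0])
        assert np.allclose(jf.y_axis, [0, -1, 0])
        assert np.linalg.det(jf.axes) > 0

    def test_orthonormal_right_handed_for_random_inputs(self, rng):
        for _ in range(20):
            kjc = rng.normal(size=3)
            hjc = kjc + rng.normal(size=3)
            z = rng.normal(size=3)
            z /= np.linalg.norm(z)
            if abs(np.dot(z, (hjc - kjc) / np.linalg.norm(hjc - kjc))) > 0.99:
                continue
            jf = build_knee_jcs(kjc, hjc, z)
            assert np.allclose(jf.axes.T @ jf.axes, np.eye(3), atol=1e-12)
            assert np.linalg.det(jf.axes) > 0

    def test_rotation_equivariance(self, rng):
        kjc, hjc = np.zeros(3), np.array([0.1, 0.4, 0.0])
        z = np.array([0.05, 0.0, 1.0])
        z /= np.linalg.norm(z)
        Q = Rotation.from_rotvec([0.2, -0.4, 0.8]).as_matrix()
        a = build_knee_jcs(kjc, hjc, z)
        b = build_knee_jcs(Q @ kjc, Q @ hjc, Q @ z)
        assert np.allclose(Q @ a.axes, b.axes, atol=1e-12)

    def test_parallel_axis_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            build_ankle_jcs([0, 0, 0.0], [0, 1, 0.0], [0, 1.0, 0])


class TestFullCalibration:
    def test_noiseless_recovery(self, tilted_session):
        """Every stored parameter matches the generator ground truth."""
        sub = tilted_session["subject"]
        cal = tilted_session["cal"]
        jc = sub.joint_centers_neutral()
        assert np.linalg.norm(cal.hjc - jc["hjc"]) < 1e-6
        assert np.linalg.norm(cal.kjc - jc["kjc"]) < 1e-6
        assert np.linalg.norm(cal.ajc - jc["ajc"]) < 1e-6
        assert np.abs(cal.jcs_knee.axes - sub.true_knee_axes).max() < 1e-6
        assert np.abs(cal.jcs_ankle.axes - sub.true_ankle_axes).max() < 1e-6

    def test_axis_sign_is_medial_to_lateral(self, tilted_session):
        assert cal_z_points_lateral(tilted_session["cal"])

    def test_missing_marker_named_in_error(self, neutral_session):
        static = neutral_session["static"]
        broken = static.subset([l for l in static.labels if l != "KNEM"])
        with pytest.raises(MissingMarkerError, match="KNEM"):
            calibrate(neutral_session["refs"], broken)

    def test_transfer_static_is_constant(self, tilted_session):
        sub = tilted_session["subject"]
        static_long = fk.simulate_static(sub, duration=0.5, rate=50)
        tf = transfer_to_trial(tilted_session["cal"], static_long)
        for arr in (tf.hjc, tf.kjc, tf.ajc):
            assert np.ptp(arr, axis=0).max() < 1e-12

    def test_transfer_equivariant_under_rigid_motion(self, tilted_session):
        from funkam.markers import MarkerTrajectorySet

        sub = tilted_session["subject"]
        static = fk.simulate_static(sub, duration=0.2, rate=50)
        Q = Rotation.from_rotvec([0.1, 0.5, -0.3]).as_matrix()
        t = np.array([0.3, -0.1, 1.2])
        moved = MarkerTrajectorySet(static.labels, static.rate, static.positions @ Q.T + t)
        a = transfer_to_trial(tilted_session["cal"], static)
        b = transfer_to_trial(tilted_session["cal"], moved)
        assert np.allclose(b.kjc, a.kjc @ Q.T + t, atol=1e-9)
        assert np.allclose(b.jcs_knee_prox, np.einsum("ij,fjk->fik", Q, a.jcs_knee_prox), atol=1e-9)

    def test_transfer_consistent_with_score_on_reference(self, tilted_session):
        """Transferred HJC in the StarArc equals SCoRE's per-frame center."""
        cal = tilted_session["cal"]
        star = tilted_session["refs"]["stararc"]
        tf = transfer_to_trial(cal, star)
        # per-frame hip center from the thigh-side SCoRE parameter
        thigh_hjc = (
            np.einsum("fij,j->fi", tf.carrier_R["thigh"], cal.hjc_in_thigh)
            + tf.carrier_t["thigh"]
        )
        gap = np.linalg.norm(tf.hjc - thigh_hjc, axis=1)
        assert gap.max() < max(5 * cal.residuals["hip_score"], 1e-9)

    def test_noisy_calibration_medians(self):
        """1 mm marker noise: HJC < 5 mm, axis errors < 1 degree (median)."""
        hjc_err, ax_err = [], []
        for seed in range(15):
            sub = fk.make_subject(seed, knee_tilt_deg=6.0)
            ns = fk.NoiseSpec(gaussian_sigma=1e-3)
            rng = np.random.default_rng(seed + 500)
            refs = {
                "stararc": fk.simulate_stararc(sub, duration=6, rate=50, noise=ns, rng=rng),
                "knee": fk.simulate_flexion_reference(sub, "knee", duration=4, rate=50, noise=ns, rng=rng),
                "ankle": fk.simulate_flexion_reference(sub, "ankle", duration=4, rate=50, noise=ns, rng=rng),
            }
            static = fk.simulate_static(sub, duration=0.2, rate=50)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cal = calibrate(refs, static)
            jc = sub.joint_centers_neutral()
            hjc_err.append(np.linalg.norm(cal.hjc - jc["hjc"]))
            ax_err.append(
                np.degrees(np.arccos(np.clip(abs(np.dot(cal.jcs_knee.z_axis, sub.true_knee_axes[:, 2])), -1, 1)))
            )
        assert np.median(hjc_err) < 5e-3
        assert np.median(ax_err) < 1.0


def cal_z_points_lateral(cal) -> bool:
    # lateral is +z in the lab at the static pose for a right-side subject
    return cal.jcs_knee.z_axis[2] > 0.9 and cal.jcs_ankle.z_axis[2] > 0.9
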