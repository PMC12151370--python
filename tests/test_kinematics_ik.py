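"""Forward kinematics, analytic Jacobian and inverse kinematics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import funkam as fk
from funkam.kinematics import batch_segment_poses, forward_markers, marker_jacobian, propagate
from funkam.ik import solve_ik_frame, solve_ik_trial
from funkam.markers import MarkerTrajectorySet
from funkam.signals import FilterSpec


@pytest.fixture(scope="module")
def model():
    return fk.make_subject(7, knee_tilt_deg=5.0).model


class TestForwardKinematics:
    def test_neutral_pose_matches_local_placements(self, model):
        """At q = 0 every segment frame is lab-aligned, so marker lab
        positions are local placements offset by the joint-center chain."""
        labels, pos = forward_markers(model, np.zeros(18))
        state = propagate(model, np.zeros(18))
        for name, st in state.segments.items():
            assert np.allclose(st.R, np.eye(3), atol=1e-12)
        i = labels.index("KNEL")
        seg = model.segments["thigh"]
        assert np.allclose(pos[i], state.segments["thigh"].p + seg.local_markers["KNEL"])

    def test_pelvis_rotation_rigidly_rotates_all_markers(self, model):
        q = np.zeros(18)
        labels, p0 = forward_markers(model, q)
        qi = model.coord_index["pelvis_rot_z"]
        q[qi] = 0.4
        _, p1 = forward_markers(model, q)
        R = Rotation.from_rotvec([0, 0, 0.4]).as_matrix()
        assert np.allclose(p1, p0 @ R.T, atol=1e-12)

    def test_batch_poses_match_per_frame(self, model, rng):
        qs = rng.normal(scale=0.2, size=(6, 18))
        batch = batch_segment_poses(model, qs)
        for f in range(6):
            state = propagate(model, qs[f])
            for name, st in state.segments.items():
                R, p = batch[name]
                assert np.allclose(R[f], st.R, atol=1e-12)
                assert np.allclose(p[f], st.p, atol=1e-12)

    def test_finite_difference_velocities(self, model, rng):
        """Propagated velocities/accelerations match numerical derivatives
        of the position-level kinematics."""
        q0 = rng.normal(scale=0.2, size=18)
        qd = rng.normal(scale=0.5, size=18)
        qdd = rng.normal(scale=1.0, size=18)
        h = 1e-5

        def com_of(qv):
            st = propagate(model, qv)
            return {n: s.com for n, s in st.segments.items()}

        state = propagate(model, q0, qd, qdd)
        cp = com_of(q0 + h * qd + 0.5 * h * h * qdd)
        cm = com_of(q0 - h * qd + 0.5 * h * h * qdd)
        c0 = com_of(q0)
        for name in cp:
            v_num = (cp[name] - cm[name]) / (2 * h)
            a_num = (cp[name] - 2 * c0[name] + cm[name]) / (h * h)
            assert np.allclose(state.segments[name].v_com, v_num, atol=1e-6)
            assert np.allclose(state.segments[name].a_com, a_num, atol=1e-4)


class TestJacobian:
    def test_matches_finite_differences(self, model, rng):
        q = rng.normal(scale=0.3, size=18)
        labels = model.marker_labels()
        state = propagate(model, q)
        J, pos = marker_jacobian(model, state, labels)
        h = 1e-7
        for k in range(18):
            dq = np.zeros(18)
            dq[k] = h
            _, pp = forward_markers(model, q + dq, labels)
            _, pm = forward_markers(model, q - dq, labels)
            J_num = (pp - pm) / (2 * h)
            assert np.abs(J[:, :, k] - J_num).max() < 1e-6


class TestIkFrame:
    def test_inverts_forward_map(self, model, rng):
        q_true = rng.normal(scale=0.25, size=18)
        labels, obs = forward_markers(model, q_true)
        q, rms, ok = solve_ik_frame(model, labels, obs, q_init=q_true + rng.normal(scale=0.05, size=18), check_observability=False)
        assert ok
        assert rms < 1e-9
        assert np.abs(q - q_true).max() < 1e-8

    def test_objective_not_worse_than_truth_on_noiseless_data(self, model, rng):
        q_true = rng.normal(scale=0.2, size=18)
        labels, obs = forward_markers(model, q_true)
        q, rms, _ = solve_ik_frame(model, labels, obs, q_init=np.zeros(18), check_observability=False)
        _, pred = forward_markers(model, q, labels)
        assert np.sum((obs - pred) ** 2) <= 1e-12

    def test_noisy_angle_error_below_half_degree(self, model):
        """1 mm marker noise perturbs leg-press joint angles < 0.5 deg median."""
        q_true = np.zeros(18)
        q_true[model.coord_index["hip_flexion"]] = np.radians(80)
        q_true[model.coord_index["knee_flexion"]] = np.radians(50)
        labels, obs0 = forward_markers(model, q_true)
        errs = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            obs = obs0 + r.normal(scale=1e-3, size=obs0.shape)
            q, _, _ = solve_ik_frame(model, labels, obs, q_init=q_true, check_observability=False)
            for cname in ("hip_flexion", "knee_flexion", "knee_adduction"):
                errs.append(abs(np.degrees(q[model.coord_index[cname]] - q_true[model.coord_index[cname]])))
        assert np.median(errs) < 0.5

    def test_observability_warning_for_thin_segments(self, model):
        labels = ["RASI", "LASI", "RPSI", "LPSI", "KNEL", "KNEM", "HEEL", "MT1", "MT5"]
        _, obs = forward_markers(model, np.zeros(18), labels)
        with pytest.warns(UserWarning, match="fewer than 3"):
            solve_ik_frame(model, labels, obs)


class TestIkTrial:
    def make_trial(self, model, q_series, rate=100.0):
        labels = model.marker_labels()
        pos = np.stack([forward_markers(model, q)[1] for q in q_series])
        return MarkerTrajectorySet(labels, rate, pos)

    def test_constant_posture_zero_derivatives(self, model):
        q0 = np.zeros(18)
        q0[model.coord_index["knee_flexion"]] = 0.5
        trial = self.make_trial(model, np.tile(q0, (60, 1)))
        traj = solve_ik_trial(model, trial)
        assert np.abs(traj.qdot).max() < 1e-9
        assert np.abs(traj.qddot).max() < 1e-9

    def test_programmed_sine_acceleration_closed_form(self, model):
        """q(t) = A sin(wt) recovers qddot = -A w^2 sin(wt) within 2 %."""
        rate, A, freq = 100.0, 0.3, 0.5
        w = 2 * np.pi * freq
        t = np.arange(300) / rate
        qs = np.zeros((300, 18))
        qi = model.coord_index["knee_flexion"]
        qs[:, qi] = 0.8 + A * np.sin(w * t)
        trial = self.make_trial(model, qs)
        traj = solve_ik_trial(model, trial)
        mid = slice(50, 250)
        expected = -A * w * w * np.sin(w * t[mid])
        assert np.abs(traj.qddot[mid, qi] - expected).max() < 0.02 * A * w * w

    def test_time_reversal_flips_velocity_keeps_acceleration(self, model):
        rate = 100.0
        t = np.arange(120) / rate
        qs = np.zeros((120, 18))
        qi = model.coord_index["hip_flexion"]
        qs[:, qi] = 0.3 * np.sin(2 * np.pi * 0.4 * t)
        fwd = solve_ik_trial(model, self.make_trial(model, qs), filter_spec=None)
        rev = solve_ik_trial(model, self.make_trial(model, qs[::-1]), filter_spec=None)
        assert np.allclose(rev.qdot[:, qi], -fwd.qdot[::-1, qi], atol=1e-8)
        assert np.allclose(rev.qddot[:, qi], fwd.qddot[::-1, qi], atol=1e-6)

    def test_warm_started_equals_cold_per_frame_solutions(self, model, rng):
        """Streaming (warm-started) solutions equal independent solves."""
        t = np.arange(30) / 100.0
        qs = np.zeros((30, 18))
        qs[:, model.coord_index["knee_flexion"]] = 0.6 + 0.2 * np.sin(2 * np.pi * t)
        trial = self.make_trial(model, qs)
        traj = solve_ik_trial(model, trial, filter_spec=None)
        for f in (0, 13, 29):
            labels = trial.labels
            q_cold, _, _ = solve_ik_frame(model, labels, trial.positions[f], q_init=qs[f] + 0.01, check_observability=False)
            assert np.abs(traj.q[f] - q_cold).max() < 1e-7

    def test_global_rigid_motion_absorbed_by_pelvis(self, model):
        """A lab-frame rigid motion changes only the pelvis coordinates."""
        q0 = np.zeros(18)
        q0[model.coord_index["knee_flexion"]] = 0.4
        labels, obs = forward_markers(model, q0)
        shift = np.array([0.25, -0.1, 0.4])
        q1, rms, _ = solve_ik_frame(model, labels, obs + shift, q_init=q0, check_observability=False)
        assert rms < 1e-9
        internal = [i for i, n in enumerate(model.coordinate_names) if not n.startswith("pelvis")]
        assert np.abs(q1[internal] - q0[internal]).max() < 1e-8
        assert np.allclose(q1[:3], shift, atol=1e-8)
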