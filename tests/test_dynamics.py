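"""Newton-Euler inverse dynamics, moment expression and normalization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import funkam as fk
from funkam.dynamics import (
    AppliedWrench,
    MomentSeries,
    WrenchSeries,
    denormalize_bwht,
    express_moment_distal,
    newton_euler_id,
    normalize_bwht,
    power_balance,
    resample_wrench,
    subtree_external_moment,
)
from funkam.kinematics import propagate
from funkam.model import Anthropometry


@pytest.fixture(scope="module")
def model():
    return fk.make_subject(2, knee_tilt_deg=5.0).model


def plate_wrench(model, q, F, C, local=np.array([0.1, -0.04, 0.01])):
    st = propagate(model, q).segments["calcaneus"]
    p = st.p + st.R @ local
    return AppliedWrench("calcaneus", F, C, p), p


class TestNewtonEuler:
    def test_static_no_load_no_gravity_all_zero(self, model):
        res = newton_euler_id(model, np.zeros(18), gravity=np.zeros(3))
        assert np.abs(res.tau).max() < 1e-12
        for m in res.joint_moment.values():
            assert np.abs(m).max() < 1e-12

    def test_static_knee_moment_equals_lever_arm_closed_form(self, model):
        """Gravity off: knee moment is (p - KJC) x F plus the plate couple."""
        F = np.array([15.0, 240.0, -40.0])
        C = np.array([0.6, -1.1, 2.0])
        q = np.zeros(18)
        q[model.coord_index["knee_flexion"]] = 0.6
        wr, p = plate_wrench(model, q, F, C)
        res = newton_euler_id(model, q, external=wr, gravity=np.zeros(3))
        closed = np.cross(p - res.joint_center["knee"], F) + C
        assert np.abs(res.joint_moment["knee"] - closed).max() < 1e-10

    def test_matches_subtree_oracle_with_dynamics(self, model, rng):
        q = rng.normal(scale=0.3, size=18)
        qd = rng.normal(scale=1.0, size=18)
        qdd = rng.normal(scale=4.0, size=18)
        wr, _ = plate_wrench(model, q, np.array([30.0, 150.0, -10.0]), np.zeros(3))
        res = newton_euler_id(model, q, qd, qdd, wr)
        state = res.state
        for joint in ("knee", "ankle", "hip", "subtalar", "mtp"):
            oracle = subtree_external_moment(model, state, joint, [wr])
            assert np.abs(res.joint_moment[joint] - oracle).max() < 1e-9

    def test_power_balance_on_dynamic_states(self, model):
        """Sum tau*qdot equals dKE/dt - gravity power - external power."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            q = r.normal(scale=0.3, size=18)
            qd = r.normal(scale=1.5, size=18)
            qdd = r.normal(scale=5.0, size=18)
            wr, _ = plate_wrench(model, q, r.normal(scale=200, size=3), r.normal(scale=5, size=3))
            res = newton_euler_id(model, q, qd, qdd, wr)
            lhs, rhs = power_balance(model, res.state, res.tau, [wr])
            assert abs(lhs - rhs) / max(abs(lhs), abs(rhs), 1.0) < 1e-10

    def test_wrench_transport_invariance(self, model, rng):
        """Moving the application point with the transported couple changes
        nothing."""
        q = rng.normal(scale=0.2, size=18)
        F = np.array([20.0, 300.0, -60.0])
        C = np.array([1.0, 0.5, -0.2])
        wr, p = plate_wrench(model, q, F, C)
        p2 = p + np.array([0.2, -0.05, 0.1])
        wr2 = AppliedWrench("calcaneus", F, C + np.cross(p - p2, F), p2)
        r1 = newton_euler_id(model, q, external=wr)
        r2 = newton_euler_id(model, q, external=wr2)
        for j in r1.joint_moment:
            assert np.abs(r1.joint_moment[j] - r2.joint_moment[j]).max() < 1e-10
        assert np.abs(r1.tau - r2.tau).max() < 1e-10

    def test_quasistatic_inertial_terms_negligible(self):
        """At the 0.025 m/s protocol speed, statics and full ID agree < 0.5 %."""
        sub = fk.make_subject(4)
        trial = fk.simulate_legpress(sub, "dynamic", rate=25)
        model = sub.model
        f = trial.markers.n_frames // 2
        q, qd, qdd = trial.q_true.q[f], trial.q_true.qdot[f], trial.q_true.qddot[f]
        wr = AppliedWrench("calcaneus", trial.wrench.force[f], trial.wrench.moment[f], trial.wrench.application_point[f])
        full = newton_euler_id(model, q, qd, qdd, wr)
        static = newton_euler_id(model, q, external=wr)
        ref = np.linalg.norm(full.joint_moment["knee"])
        assert np.linalg.norm(full.joint_moment["knee"] - static.joint_moment["knee"]) < 0.005 * ref


class TestMomentExpression:
    def test_lab_frame_identity(self, rng):
        m = rng.normal(size=3)
        assert np.allclose(express_moment_distal(m, np.eye(3)), m)

    def test_sagittal_moment_has_zero_frontal_component(self):
        """A pure flexion-axis moment projects to zero on the adduction axis
        in a frame rotated about that flexion axis."""
        axes = Rotation.from_rotvec([0, 0, 0.7]).as_matrix()  # rotated about z
        m = 12.0 * axes[:, 2]  # moment purely about the frame z (flexion) axis
        local = express_moment_distal(m, axes)
        assert abs(local[0]) < 1e-12 and abs(local[1]) < 1e-12

    def test_equals_projection_on_axis_columns(self, rng):
        axes = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        m = rng.normal(size=3)
        local = express_moment_distal(m, axes)
        for k in range(3):
            assert abs(local[k] - m @ axes[:, k]) < 1e-12


class TestNormalization:
    def test_zero_maps_to_zero(self):
        ms = MomentSeries(np.arange(3.0), {}, np.zeros(3))
        out = normalize_bwht(ms, Anthropometry(64.0, 1.74))
        assert np.all(out.eam == 0) and out.units == "%BWHt"

    def test_reference_arithmetic(self):
        """10.92 N*m at 64 kg / 1.74 m is 1.0 %BWHt with g = 9.81."""
        ms = MomentSeries(np.zeros(1), {}, np.array([10.92]))
        out = normalize_bwht(ms, Anthropometry(64.0, 1.74))
        assert abs(out.eam[0] - 10.92 / (64 * 9.81 * 1.74) * 100) < 1e-12
        assert abs(out.eam[0] - 1.0) < 1e-3

    def test_round_trip_identity(self, rng):
        ms = MomentSeries(np.arange(4.0), {"knee": rng.normal(size=(4, 3))}, rng.normal(size=4))
        a = Anthropometry(70.0, 1.8)
        back = denormalize_bwht(normalize_bwht(ms, a), a)
        assert np.allclose(back.eam, ms.eam, atol=1e-12)

    def test_doubling_mass_and_height_quarters_normalized_value(self):
        ms = MomentSeries(np.zeros(1), {}, np.array([50.0]))
        a1 = normalize_bwht(ms, Anthropometry(64.0, 1.74)).eam[0]
        a2 = normalize_bwht(ms, Anthropometry(128.0, 3.48)).eam[0]
        assert abs(a2 - a1 / 4.0) < 1e-12


class TestWrenchSeries:
    def test_resample_preserves_plateau(self):
        t = np.arange(4000) / 2000.0
        f = np.column_stack([np.zeros_like(t), np.full_like(t, 700.0), np.zeros_like(t)])
        ws = WrenchSeries(t, f, np.zeros_like(f), np.tile([0.4, 0.0, 0.1], (len(t), 1)))
        out = resample_wrench(ws, 100.0)
        assert abs(out.rate - 100.0) < 1e-6
        assert np.abs(out.force[:, 1] - 700.0).max() < 1e-6

    def test_non_monotone_time_rejected(self):
        with pytest.raises(Exception):
            WrenchSeries(np.array([0.0, 0.0, 1.0]), np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))


class TestRefPipeline:
    def test_ref_matches_generator_truth_on_static_trial(self, tilted_session):
        from funkam.dynamics import ref_pipeline
        from tests.conftest import conditioned_legpress

        trial, markers = conditioned_legpress(tilted_session, "static", duration=2.0)
        angles, ms = ref_pipeline(markers, tilted_session["cal"], trial.wrench, trial.anthro)
        # ignore the ramp edges where finite differences see the force onset
        sl = slice(30, -2)
        err = ms.eam[sl] - trial.truth.eam[sl]
        assert np.sqrt(np.mean(err**2)) < 1e-3
        assert abs(np.degrees(angles["knee_flexion"][40]) - 50.0) < 1e-6

    def test_ref_zero_force_static_matches_gravity_statics(self, tilted_session):
        """With no plate load the knee moment is the weight lever of the
        distal segments."""
        from funkam.dynamics import ref_pipeline
        from tests.conftest import conditioned_legpress

        trial, markers = conditioned_legpress(tilted_session, "static", duration=2.0)
        angles, ms = ref_pipeline(markers, tilted_session["cal"], None, trial.anthro)
        model = tilted_session["subject"].model
        q = trial.q_true.q[40]
        grav = newton_euler_id(model, q)
        eam_truth = None
        state = grav.state
        prox = state.segments["thigh"].R @ model.joint_by_name["knee"].parent_placement.rotation
        from funkam.dynamics import floating_adduction_axis

        eam_truth = grav.joint_moment["knee"] @ floating_adduction_axis(
            prox, q[model.coord_index["knee_flexion"]]
        )
        scale = 100.0 / (trial.anthro.mass * 9.81 * trial.anthro.height)
        assert abs(ms.eam[40] - eam_truth * scale) < 1e-3
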