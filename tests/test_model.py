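"""Generic model construction, scaling laws and functional-axis integration."""

import numpy as np
import pytest

import funkam as fk
from funkam.anthropometry import SEGMENT_TABLE
from funkam.errors import ValidationError
from funkam.kinematics import propagate
from funkam.model import (
    Anthropometry,
    apply_scaling,
    integrate_far_fun1,
    integrate_far_fun2,
    make_generic_model,
    scale_model,
)


class TestGenericModel:
    def test_eighteen_coordinates(self, generic_model):
        assert generic_model.n_coordinates == 18

    def test_seven_segments(self, generic_model):
        assert generic_model.n_segments == 7
        assert set(generic_model.segments) == {
            "pelvis", "torso", "thigh", "shank", "talus", "calcaneus", "toes",
        }

    def test_knee_has_three_rotational_coordinates(self, generic_model):
        knee = generic_model.joint_by_name["knee"]
        assert len(knee.coordinates) == 3
        assert all(c.kind == "rot" for c in knee.coordinates)

    def test_joint_dof_layout(self, generic_model):
        dof = {j.name: len(j.coordinates) for j in generic_model.joints}
        assert dof == {"ground": 6, "back": 3, "hip": 3, "knee": 3, "ankle": 1, "subtalar": 1, "mtp": 1}

    def test_generic_mass_fractions_sum_to_one(self):
        assert abs(sum(v[0] for v in SEGMENT_TABLE.values()) - 1.0) < 1e-12

    def test_placements_orthonormal(self, generic_model):
        for j in generic_model.joints:
            for P in (j.parent_placement, j.child_placement):
                P.validate(1e-10)


class TestScaling:
    def test_identity_subject_unchanged(self, generic_model):
        """A subject identical to the generic model gives unit scale factors."""
        sub = fk.make_subject(0, anthro=Anthropometry(64.0, 1.74), segment_scale_jitter=0.0)
        static = fk.simulate_static(sub, duration=0.1, rate=50)
        jc = sub.joint_centers_neutral()
        scaled = scale_model(generic_model, jc["hjc"], jc["kjc"], jc["ajc"], static, sub.anthro)
        for name, seg in scaled.segments.items():
            gen = generic_model.segments[name]
            assert abs(seg.mass - gen.mass) < 1e-9
            assert np.allclose(seg.com, gen.com, atol=1e-9)
            assert np.allclose(seg.inertia, gen.inertia, atol=1e-9)

    def test_uniform_scaling_laws(self, generic_model):
        """1.1x lengths with a mass ratio scale inertia by ratio * 1.21."""
        anthro = Anthropometry(80.0, 1.74 * 1.1)
        factors = {name: 1.1 for name in generic_model.segments}
        scaled = apply_scaling(generic_model, factors, anthro)
        for name, seg in scaled.segments.items():
            gen = generic_model.segments[name]
            mass_ratio = (SEGMENT_TABLE[name][0] * 80.0) / gen.mass
            assert np.allclose(seg.com, gen.com * 1.1)
            assert np.allclose(seg.inertia, gen.inertia * mass_ratio * 1.21)

    def test_total_mass_conserved(self, tilted_session):
        anthro = tilted_session["subject"].anthro
        for variant in ("con", "fun1", "fun2"):
            assert abs(tilted_session[variant].total_mass() - anthro.mass) < 1e-9

    def test_markers_match_static_after_adjustment(self, tilted_session):
        """Model at the IK solution of the static pose reproduces markers."""
        from funkam.ik import solve_ik_frame

        static = tilted_session["static"]
        model = tilted_session["con"]
        labels = [l for l in static.labels if l in model.marker_labels()]
        obs = np.array([static.positions[0, static.labels.index(l)] for l in labels])
        q, rms, ok = solve_ik_frame(model, labels, obs, check_observability=False)
        assert ok and rms < 1e-9

    def test_missing_anthropometry_rejected(self):
        with pytest.raises(ValidationError):
            Anthropometry(0.0, 1.74)


class TestFarIntegration:
    def test_identity_calibration_reduces_to_con(self, neutral_session):
        """Zero axis tilt: FUN 1 and FUN 2 equal the CON model."""
        con, fun1, fun2 = (neutral_session[k] for k in ("con", "fun1", "fun2"))
        for variant in (fun1, fun2):
            for jname in ("knee", "ankle"):
                a = con.joint_by_name[jname]
                b = variant.joint_by_name[jname]
                assert np.abs(a.parent_placement.rotation - b.parent_placement.rotation).max() < 1e-10
                assert np.abs(a.child_placement.rotation - b.child_placement.rotation).max() < 1e-10

    def test_fun1_reorients_proximal_frames_only(self, tilted_session):
        con, fun1 = tilted_session["con"], tilted_session["fun1"]
        knee_c, knee_f = con.joint_by_name["knee"], fun1.joint_by_name["knee"]
        assert np.abs(knee_c.parent_placement.rotation - knee_f.parent_placement.rotation).max() > 1e-3
        assert np.array_equal(knee_c.child_placement.rotation, knee_f.child_placement.rotation)
        assert np.allclose(knee_c.parent_placement.translation, knee_f.parent_placement.translation)

    def test_fun2_matches_true_subject_placements(self, tilted_session):
        """Both-frame integration reproduces the tilted true joint frames."""
        sub = tilted_session["subject"]
        fun2 = tilted_session["fun2"]
        for jname in ("knee", "ankle"):
            true_j = sub.model.joint_by_name[jname]
            est_j = fun2.joint_by_name[jname]
            assert np.abs(est_j.parent_placement.rotation - true_j.parent_placement.rotation).max() < 1e-9
            assert np.abs(est_j.child_placement.rotation - true_j.child_placement.rotation).max() < 1e-9

    def test_fun1_reorientation_matches_prescribed_tilt(self, generic_model):
        """A pure frontal-plane tilt reappears exactly in the femur frame."""
        tilt = 10.0
        sub = fk.make_subject(3, knee_tilt_deg=tilt, segment_scale_jitter=0.0)
        sess_static = fk.simulate_static(sub, duration=0.1, rate=50)
        refs = {
            "stararc": fk.simulate_stararc(sub, duration=6, rate=50),
            "knee": fk.simulate_flexion_reference(sub, "knee", duration=4, rate=50),
            "ankle": fk.simulate_flexion_reference(sub, "ankle", duration=4, rate=50),
        }
        from funkam.calibration import calibrate

        cal = calibrate(refs, sess_static)
        fun1 = integrate_far_fun1(generic_model, cal, sess_static, sub.anthro)
        got = fun1.joint_by_name["knee"].parent_placement.rotation
        want = sub.model.joint_by_name["knee"].parent_placement.rotation
        assert np.abs(got - want).max() < 1e-9

    def test_fun2_marker_placements_equal_con(self, tilted_session):
        con, fun2 = tilted_session["con"], tilted_session["fun2"]
        for name in con.segments:
            for lbl, p in con.segments[name].local_markers.items():
                assert np.array_equal(p, fun2.segments[name].local_markers[lbl])

    def test_joint_frames_stay_orthonormal(self, tilted_session):
        for variant in ("con", "fun1", "fun2"):
            for j in tilted_session[variant].joints:
                j.parent_placement.validate(1e-8)
                j.child_placement.validate(1e-8)

    def test_all_variants_keep_18_coordinates(self, tilted_session):
        for variant in ("con", "fun1", "fun2"):
            assert tilted_session[variant].n_coordinates == 18

    def test_fun_knee_axes_agree_in_lab_at_static(self, tilted_session):
        """FUN 1 and FUN 2 femur-side knee frames coincide at the reference pose.

        The proximal placements are built from the same functional JCS, so
        they agree exactly in the segment frame; in the lab they agree to the
        small static misfit FUN 1 incurs at its generic distal ankle frame.
        """
        from funkam.ik import solve_ik_frame

        fun1, fun2 = tilted_session["fun1"], tilted_session["fun2"]
        assert np.abs(
            fun1.joint_by_name["knee"].parent_placement.rotation
            - fun2.joint_by_name["knee"].parent_placement.rotation
        ).max() < 1e-12

        static = tilted_session["static"]
        axes = {}
        for variant, model in (("fun1", fun1), ("fun2", fun2)):
            labels = [l for l in static.labels if l in model.marker_labels()]
            obs = np.array([static.positions[0, static.labels.index(l)] for l in labels])
            q, _, _ = solve_ik_frame(model, labels, obs, check_observability=False)
            state = propagate(model, q)
            axes[variant] = state.segments["thigh"].R @ model.joint_by_name["knee"].parent_placement.rotation
        assert np.abs(axes["fun1"] - axes["fun2"]).max() < 5e-3
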