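"""Base-model construction, morphing workflow steps and osim/JSON output."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scolimorph import errors
from scolimorph import model_builder as mb
from scolimorph import synthetic as syn
from scolimorph.geometry import BodyFrame, fit_sphere, select_anterior_nodes
from scolimorph.landmarks import Landmark, LandmarkSet

TABLE_TRANSLATIONAL = (149_000.0, 1_890_000.0, 135_000.0)
TABLE_ROTATIONAL = (68.8, 291.0, 51.0)


class TestBaseModel:
    def test_default_bushings_carry_literature_disc_properties(self, base_model):
        assert base_model.ivj_names()  # at least one IVJ
        for name in base_model.ivj_names():
            props = base_model.bushings[name].props
            assert props.translational_stiffness == TABLE_TRANSLATIONAL
            assert props.rotational_stiffness == TABLE_ROTATIONAL
            assert props.translational_damping == (1000.0, 1000.0, 1000.0)
            assert props.rotational_damping == (2.3, 2.3, 2.3)

    def test_every_ivj_has_six_dof(self, base_model):
        for joint in base_model.joints:
            assert joint.dof == 6

    def test_chain_is_pelvis_sacrum_then_caudal_to_cranial(self, base_model):
        chain = [(j.parent, j.child) for j in base_model.joints]
        assert chain[0] == ("PELVIS", "SACRUM")
        assert chain[1] == ("SACRUM", "L5")
        assert chain[-1][1] == base_model.levels[0]  # most cranial level

    def test_custom_doubled_stiffness_propagates(self, template):
        props = mb.BushingProperties(
            translational_stiffness=tuple(2 * v for v in TABLE_TRANSLATIONAL),
            rotational_stiffness=tuple(2 * v for v in TABLE_ROTATIONAL),
        )
        model = mb.build_base_model(template, props=props)
        for name in model.ivj_names():
            got = model.bushings[name].props
            assert got.translational_stiffness == tuple(2 * v for v in TABLE_TRANSLATIONAL)
            assert got.rotational_stiffness == tuple(2 * v for v in TABLE_ROTATIONAL)
        # joints themselves unchanged by bushing properties
        base = mb.build_base_model(template)
        for j1, j2 in zip(model.joints, base.joints):
            np.testing.assert_allclose(j1.origin, j2.origin)

    def test_every_vertebra_has_wrap_sphere(self, base_model):
        for level in base_model.levels:
            sphere = base_model.bodies[level].wrap_sphere
            assert sphere is not None and sphere.radius > 0

    def test_nonpositive_properties_rejected(self):
        with pytest.raises(ValueError):
            mb.BushingProperties(translational_stiffness=(0.0, 1.0, 1.0))


def _landmark_set(level, positions):
    return LandmarkSet(
        [Landmark(level, c, p) for c, p in positions.items()], frame="MODEL"
    )


def _box_landmarks(level, ap=32.0, is_h=28.0, rl=40.0):
    y, hx, hz = is_h / 2.0, ap / 2.0, rl / 2.0
    return {
        "S1": np.array([hx, y, 0.0]), "S2": np.array([-hx, y, 0.0]),
        "S3": np.array([hx, -y, 0.0]), "S4": np.array([-hx, -y, 0.0]),
        "S5": np.array([0.0, y, hz]), "S6": np.array([0.0, y, -hz]),
        "S7": np.array([0.0, -y, hz]), "S8": np.array([0.0, -y, -hz]),
        "JM1": np.array([-hx, 5.0, 10.0]), "JM2": np.array([-hx, -5.0, 10.0]),
        "JM3": np.array([-hx, 5.0, -10.0]), "JM4": np.array([-hx, -5.0, -10.0]),
        "JM5": np.array([0.0, y, 0.0]), "JM6": np.array([0.0, -y, 0.0]),
    }


class TestScaleFactors:
    def test_identical_landmarks_give_unit_factors(self):
        ls = _landmark_set("L3", _box_landmarks("L3"))
        assert mb.compute_scale_factors(ls, ls, "L3") == (1.0, 1.0, 1.0)

    def test_uniform_scaling_is_recovered(self):
        pos = _box_landmarks("L3")
        model = _landmark_set("L3", pos)
        subject = _landmark_set("L3", {c: 1.5 * p for c, p in pos.items()})
        np.testing.assert_allclose(
            mb.compute_scale_factors(model, subject, "L3"), (1.5, 1.5, 1.5)
        )

    def test_ap_only_change_gives_hand_computed_ratio(self):
        # model AP span 32 mm, subject AP span 40 mm, IS/RL equal -> (1.25, 1, 1)
        model = _landmark_set("L3", _box_landmarks("L3", ap=32.0))
        subject_pos = _box_landmarks("L3", ap=40.0)
        subject = _landmark_set("L3", subject_pos)
        ap, is_f, rl = mb.compute_scale_factors(model, subject, "L3")
        np.testing.assert_allclose((ap, is_f, rl), (1.25, 1.0, 1.0))

    def test_incomplete_set_rejected(self):
        pos = _box_landmarks("L3")
        ls = _landmark_set("L3", pos)
        del pos["S5"]
        partial = _landmark_set("L3", pos)
        with pytest.raises(errors.IncompleteLandmarksError):
            mb.compute_scale_factors(ls, partial, "L3")

    def test_zero_span_rejected(self):
        pos = _box_landmarks("L3")
        degenerate = dict(pos)
        for c in ("S1", "S2", "S3", "S4"):
            degenerate[c] = np.zeros(3)
        with pytest.raises(errors.ZeroDistanceError):
            mb.compute_scale_factors(
                _landmark_set("L3", degenerate), _landmark_set("L3", pos), "L3"
            )


class TestApplyScaling:
    def test_unit_factors_and_equal_mass_are_a_noop(self, base_model):
        sf = mb.ScaleFactors({lvl: (1.0, 1.0, 1.0) for lvl in base_model.levels})
        scaled = mb.apply_scaling(
            base_model, sf, subject_mass=base_model.total_mass
        )
        for name, body in base_model.bodies.items():
            np.testing.assert_array_equal(scaled.bodies[name].mass, body.mass)
            for c in body.markers:
                np.testing.assert_array_equal(scaled.bodies[name].markers[c], body.markers[c])
            if body.mesh is not None:
                np.testing.assert_array_equal(
                    scaled.bodies[name].mesh.vertices, body.mesh.vertices
                )

    def test_mass_scaling_conserves_subject_mass(self, base_model):
        sf = mb.ScaleFactors({lvl: (1.0, 1.0, 1.0) for lvl in base_model.levels})
        scaled = mb.apply_scaling(base_model, sf, subject_mass=75.0, template_mass=60.0)
        for name, body in base_model.bodies.items():
            assert scaled.bodies[name].mass == pytest.approx(body.mass * 1.25)
        assert scaled.total_mass == pytest.approx(
            75.0 * base_model.total_mass / 60.0, abs=1e-9
        )
        # with the template's own mass as reference the total equals the subject mass
        scaled2 = mb.apply_scaling(base_model, sf, subject_mass=75.0)
        assert scaled2.total_mass == pytest.approx(75.0, abs=1e-9)

    def test_sacrum_geometry_is_never_scaled(self, base_model):
        sf = mb.ScaleFactors({lvl: (2.0, 2.0, 2.0) for lvl in base_model.levels})
        scaled = mb.apply_scaling(base_model, sf, subject_mass=base_model.total_mass)
        np.testing.assert_array_equal(
            scaled.bodies["SACRUM"].mesh.vertices, base_model.bodies["SACRUM"].mesh.vertices
        )

    def test_wrap_sphere_is_refit_to_scaled_mesh(self, base_model):
        sf = mb.ScaleFactors(
            {lvl: ((2.0, 1.0, 1.0) if lvl == "L3" else (1.0, 1.0, 1.0))
             for lvl in base_model.levels}
        )
        scaled = mb.apply_scaling(base_model, sf, subject_mass=base_model.total_mass)
        body = scaled.bodies["L3"]
        idx = select_anterior_nodes(body.mesh, BodyFrame.identity())
        oracle = fit_sphere(body.mesh.vertices[idx])
        np.testing.assert_allclose(body.wrap_sphere.centre, oracle.centre, atol=1e-9)
        assert body.wrap_sphere.radius == pytest.approx(oracle.radius)

    def test_isotropic_scaling_scales_wrap_sphere_radius(self, base_model):
        sf = mb.ScaleFactors(
            {lvl: ((1.5, 1.5, 1.5) if lvl == "L3" else (1.0, 1.0, 1.0))
             for lvl in base_model.levels}
        )
        scaled = mb.apply_scaling(base_model, sf, subject_mass=base_model.total_mass)
        assert scaled.bodies["L3"].wrap_sphere.radius == pytest.approx(
            1.5 * base_model.bodies["L3"].wrap_sphere.radius
        )


def _promontory(slope_deg, length=50.0):
    s = np.radians(slope_deg)
    post = np.array([0.0, 90.0, 0.0])
    return post + length * np.array([np.cos(s), np.sin(s), 0.0]), post


class TestAlignSacrum:
    def test_equal_slope_is_a_noop(self, base_model, template):
        sp_ant, sp_post = _promontory(template.sacral_slope_deg)
        aligned = mb.align_sacrum(base_model, sp_ant, sp_post)
        np.testing.assert_allclose(
            aligned.bodies["SACRUM"].pose_r, base_model.bodies["SACRUM"].pose_r, atol=1e-12
        )

    def test_subject_slope_is_matched_exactly(self, base_model, template):
        # template slope 40 deg, subject 27.7 deg -> -12.3 deg pitch applied
        sp_ant, sp_post = _promontory(27.7)
        aligned = mb.align_sacrum(base_model, sp_ant, sp_post)
        rot = aligned.bodies["SACRUM"].pose_r @ base_model.bodies["SACRUM"].pose_r.T
        angle = np.degrees(Rotation.from_matrix(rot).as_rotvec())
        np.testing.assert_allclose(angle, [0.0, 0.0, 27.7 - template.sacral_slope_deg],
                                   atol=1e-9)
        sac = aligned.bodies["SACRUM"]
        v = sac.to_global(sac.markers["SP_ANT"]) - sac.to_global(sac.markers["SP_POST"])
        assert np.degrees(np.arctan2(v[1], v[0])) == pytest.approx(27.7, abs=1e-9)

    def test_idempotent(self, base_model):
        sp_ant, sp_post = _promontory(27.7)
        once = mb.align_sacrum(base_model, sp_ant, sp_post)
        twice = mb.align_sacrum(once, sp_ant, sp_post)
        for name in once.bodies:
            np.testing.assert_allclose(
                twice.bodies[name].pose_r, once.bodies[name].pose_r, atol=1e-9
            )
            np.testing.assert_allclose(
                twice.bodies[name].pose_t, once.bodies[name].pose_t, atol=1e-9
            )

    def test_vertebrae_follow_the_sacrum_rotation(self, base_model):
        sp_ant, sp_post = _promontory(27.7)
        aligned = mb.align_sacrum(base_model, sp_ant, sp_post)
        for lvl in base_model.levels:
            assert not np.allclose(
                aligned.bodies[lvl].pose_t, base_model.bodies[lvl].pose_t
            )
        np.testing.assert_array_equal(
            aligned.bodies["PELVIS"].pose_t, base_model.bodies["PELVIS"].pose_t
        )

    def test_missing_landmarks_rejected(self, base_model):
        with pytest.raises(errors.MissingLandmarkError):
            mb.align_sacrum(base_model, None, None)


class TestDefineJointPose:
    def test_stacked_unrotated_vertebrae_give_identity_axes(self, base_model):
        ls = base_model.landmark_set()
        joint = mb.define_joint_pose(ls, "L4", "L3")
        np.testing.assert_allclose(joint.axes, np.eye(3), atol=1e-12)
        expected = 0.5 * (
            base_model.marker_global("L4", "JM5") + base_model.marker_global("L3", "JM6")
        )
        np.testing.assert_allclose(joint.origin, expected, atol=1e-12)
        assert joint.dof == 6

    def test_lateral_tilt_of_one_vertebra_is_averaged(self, base_model):
        ls = base_model.landmark_set()
        r = Rotation.from_euler("x", 10.0, degrees=True).as_matrix()
        centre = base_model.bodies["L3"].pose_t
        tilted = LandmarkSet(
            [
                Landmark(lm.bone, lm.name,
                         centre + r @ (lm.position - centre)
                         if lm.bone == "L3" else lm.position)
                for lm in ls
            ],
            frame="MODEL",
        )
        joint = mb.define_joint_pose(tilted, "L4", "L3")
        rl = joint.axes[:, 2]
        # the joint RL bisects the two vertebrae's RL directions: 5 deg from
        # both the untilted and the tilted axis
        tilted_rl = r @ np.array([0.0, 0.0, 1.0])
        for reference in (np.array([0.0, 0.0, 1.0]), tilted_rl):
            angle = np.degrees(np.arccos(np.clip(abs(rl @ reference), -1, 1)))
            assert angle == pytest.approx(5.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rigid_rotation_equivariance(self, base_model, seed):
        ls = base_model.landmark_set()
        r = Rotation.random(random_state=seed).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved = LandmarkSet(
            [Landmark(lm.bone, lm.name, r @ lm.position + t) for lm in ls],
            frame="MODEL",
        )
        j0 = mb.define_joint_pose(ls, "L2", "L1")
        j1 = mb.define_joint_pose(moved, "L2", "L1")
        np.testing.assert_allclose(j1.origin, r @ j0.origin + t, atol=1e-9)
        np.testing.assert_allclose(j1.axes, r @ j0.axes, atol=1e-9)

    def test_missing_landmarks_rejected(self, base_model):
        ls = LandmarkSet([], frame="MODEL")
        with pytest.raises(errors.MissingLandmarkError):
            mb.define_joint_pose(ls, "L4", "L3")


class TestRealignment:
    def test_self_morphing_is_identity(self, template, base_model):
        morphed = mb.build_subject_model(
            template, base_model.landmark_set(), subject_mass=base_model.total_mass
        )
        for name, body in base_model.bodies.items():
            np.testing.assert_allclose(
                morphed.bodies[name].pose_t, body.pose_t, atol=1e-6
            )
            np.testing.assert_allclose(
                morphed.bodies[name].pose_r, body.pose_r, atol=1e-6
            )

    def test_prescribed_wedge_rotations_are_recovered(self, scoliotic_subject, morphed_model):
        _, truth = scoliotic_subject
        for lvl in truth.spec.levels:
            residual = Rotation.from_matrix(
                morphed_model.bodies[lvl].pose_r @ truth.rotations[lvl].T
            ).as_rotvec()
            assert np.degrees(np.linalg.norm(residual)) < 0.1

    def test_endplate_centres_match_palpations(self, scoliotic_subject, morphed_model):
        _, truth = scoliotic_subject
        for lvl in truth.spec.levels:
            for code in ("JM5", "JM6"):
                np.testing.assert_allclose(
                    morphed_model.marker_global(lvl, code),
                    truth.landmarks_model.get(lvl, code),
                    atol=1e-6,
                )

    def test_morphing_is_idempotent_under_repalpation(self, scoliotic_subject, morphed_model):
        _, truth = scoliotic_subject
        repalpated = morphed_model.landmark_set()
        again = mb.build_subject_model(truth.template, repalpated)
        for name in morphed_model.bodies:
            np.testing.assert_allclose(
                again.bodies[name].pose_t, morphed_model.bodies[name].pose_t, atol=1e-6
            )
            np.testing.assert_allclose(
                again.bodies[name].pose_r, morphed_model.bodies[name].pose_r, atol=1e-6
            )

    def test_subject_mass_is_conserved(self, morphed_model):
        assert morphed_model.total_mass == pytest.approx(75.0, abs=1e-9)

    def test_incomplete_landmarks_rejected(self, template):
        ls = LandmarkSet(
            [Landmark("L3", "S1", (0.0, 0.0, 0.0))], frame="MODEL"
        )
        with pytest.raises(errors.IncompleteLandmarksError):
            mb.build_subject_model(template, ls)


class TestBushings:
    def test_zero_preload_at_construction_pose(self, morphed_model):
        for name in morphed_model.ivj_names():
            d = mb.bushing_deflection(morphed_model, name)
            np.testing.assert_allclose(d, np.zeros(6), atol=1e-9)

    def test_ap_millimetre_gives_hookes_law_force(self, morphed_model):
        # 149000 N/m x 0.001 m = 149 N
        model = morphed_model.copy()
        joint = model.joint("l4_l3")
        model.bodies["L3"].pose_t = model.bodies["L3"].pose_t + joint.axes[:, 0] * 1.0
        force, moment = mb.bushing_force(model, "l4_l3")
        np.testing.assert_allclose(force, [149.0, 0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(moment, np.zeros(3), atol=1e-9)

    def test_pure_flexion_gives_hookes_law_moment(self, morphed_model):
        # 51.0 N*m/rad x 0.01 rad = 0.51 N*m
        model = morphed_model.copy()
        joint = model.joint("l4_l3")
        r = Rotation.from_rotvec(joint.axes[:, 2] * 0.01).as_matrix()
        body = model.bodies["L3"]
        body.pose_r = r @ body.pose_r
        body.pose_t = joint.origin + r @ (body.pose_t - joint.origin)
        force, moment = mb.bushing_force(model, "l4_l3")
        np.testing.assert_allclose(moment, [0.0, 0.0, 0.51], atol=1e-9)
        np.testing.assert_allclose(force, np.zeros(3), atol=1e-6)


class TestMusclePaths:
    def test_no_wrap_sphere_penetration_after_morphing(self, morphed_model):
        assert mb.check_muscle_paths(morphed_model, tolerance=0.5) == []

    def test_penetrating_segment_is_detected(self, morphed_model):
        model = morphed_model.copy()
        body = model.bodies["L3"]
        centre = body.to_global(body.wrap_sphere.centre)
        from scolimorph.template import MusclePath

        model.muscle_paths.append(
            MusclePath(
                name="through_l3",
                points=[
                    ("L3", body.to_local(centre + np.array([0.0, -60.0, 0.0]))),
                    ("L3", body.to_local(centre + np.array([0.0, 60.0, 0.0]))),
                ],
            )
        )
        hits = mb.check_muscle_paths(model)
        assert any(v["muscle"] == "through_l3" and v["level"] == "L3" for v in hits)


class TestSerialisation:
    def test_json_roundtrip_is_exact(self, morphed_model, tmp_path):
        path = tmp_path / "model.json"
        morphed_model.save_json(path)
        again = mb.SpineModel.load_json(path)
        assert again.to_dict() == morphed_model.to_dict()

    def test_osim_has_one_bushing_per_ivj(self, morphed_model, tmp_path):
        import xml.etree.ElementTree as ET

        path = tmp_path / "model.osim"
        mb.write_osim(morphed_model, path)
        root = ET.parse(path).getroot()
        bushings = root.findall(".//BushingForce")
        assert len(bushings) == len(morphed_model.ivj_names())

    def test_full_t1_l5_chain_has_one_bushing_per_ivj(self):
        # chain-length oracle: 17 vertebrae T1..L5 -> 16 inter-vertebral
        # joints plus the lumbosacral joint = 17 IVJs, one bushing each
        levels = tuple([f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)])
        model = mb.build_base_model(syn.generate_template(syn.SpineSpec(levels=levels)))
        assert len(model.ivj_names()) == len(levels) == 17
        assert len(model.bushings) == len(model.ivj_names())

    def test_osim_validates_against_dialect(self, morphed_model, tmp_path):
        path = tmp_path / "model.osim"
        mb.write_osim(morphed_model, path)
        assert mb.validate_osim(path)

    def test_osim_writing_is_deterministic(self, morphed_model, tmp_path):
        mb.write_osim(morphed_model, tmp_path / "a.osim")
        mb.write_osim(morphed_model, tmp_path / "b.osim")
        assert (tmp_path / "a.osim").read_bytes() == (tmp_path / "b.osim").read_bytes()
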