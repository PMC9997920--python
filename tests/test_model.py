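"""Model builders, invariants and editing operations."""

import numpy as np
import pytest

import landsim as ls
from landsim.model import (DEFAULT_GROUPING, RIGHT_LIMB_LOCKED_POSE,
                           SUBJECT_MASS, build_reduced3d_model,
                           lock_coordinates, save_model, load_model)


class TestPlanarBuilder:
    def test_structure(self, planar_model):
        assert len(planar_model.coordinates) == 9
        assert len(planar_model.muscles) == 16
        # eight muscle-tendon actuators per leg
        assert sum(m.name.endswith("_l") for m in planar_model.muscles) == 8

    def test_total_mass_is_subject_mass(self, planar_model):
        assert planar_model.total_mass == pytest.approx(SUBJECT_MASS, abs=1e-6)

    def test_leg_length_consistent_with_stature(self, planar_model):
        # femur + tibia + ankle height reproduce a 1.80 m subject's
        # standing hip height (~0.53 stature)
        femur = planar_model.segment("femur_l")
        tibia = planar_model.segment("tibia_l")
        leg = femur.length + tibia.length
        assert 0.50 * 1.8 < leg + 0.07 < 0.56 * 1.8
        assert planar_model.subject_height == pytest.approx(1.8)

    def test_builder_output_is_valid(self, planar_model):
        assert ls.validate_model(planar_model) == []

    def test_contact_on_both_feet(self, planar_model):
        sides = {s.name[0] for s in planar_model.contact_spheres}
        assert sides == {"l", "r"}


class TestReduced3dBuilder:
    def test_defines_23_coordinates(self, model3d):
        assert len(model3d.coordinates) == 23

    def test_five_spheres_per_foot(self, model3d):
        left = [s for s in model3d.contact_spheres if s.name.startswith("l")]
        right = [s for s in model3d.contact_spheres if s.name.startswith("r")]
        assert len(left) == 5 and len(right) == 5
        # one under the toes, four under the hindfoot
        assert sum("toe" in s.name for s in left) == 1

    def test_no_right_leg_muscles(self, model3d):
        assert all(not m.name.endswith("_r") for m in model3d.muscles)
        assert len(model3d.muscles) == 12

    def test_right_limb_locked_at_stage1_pose(self, model3d):
        for nm, val in RIGHT_LIMB_LOCKED_POSE.items():
            c = model3d.coordinate(nm)
            assert c.locked and c.locked_value == pytest.approx(val)

    def test_total_mass(self, model3d):
        assert model3d.total_mass == pytest.approx(SUBJECT_MASS, abs=1e-6)

    def test_reserve_on_every_unlocked_coordinate(self, model3d):
        reserved = {r.coordinate for r in model3d.reserves}
        unlocked = {c.name for c in model3d.unlocked_coordinates}
        assert reserved == unlocked

    def test_valid(self, model3d):
        assert ls.validate_model(model3d) == []

    def test_knee_is_a_hinge(self, planar_model, model3d):
        for model in (planar_model, model3d):
            knee = [c for c in model.coordinates if c.joint == "knee_l"]
            assert len(knee) == 1 and knee[0].kind == "rotational"

    @pytest.mark.parametrize("grouping, err", [
        ({"quadriceps": ("vasti_l",)}, ">= 6"),
        ({g: DEFAULT_GROUPING[g] for g in list(DEFAULT_GROUPING)[:6]
          if g != "quadriceps"}, "quadriceps"),
        ({**DEFAULT_GROUPING, "other": ("nonexistent",)}, "unknown muscle"),
    ])
    def test_invalid_grouping_rejected(self, grouping, err):
        if "quadriceps" in err:
            grouping = {g: v for g, v in DEFAULT_GROUPING.items()
                        if g != "quadriceps"}
        with pytest.raises(ValueError, match=err):
            build_reduced3d_model(grouping)


class TestValidate:
    def test_negative_f0_flagged(self, planar_model):
        from dataclasses import replace

        bad = replace(planar_model, muscles=(
            replace(planar_model.muscles[0], F0=-1.0),
            *planar_model.muscles[1:]))
        violations = ls.validate_model(bad)
        assert len(violations) == 1
        assert planar_model.muscles[0].name in violations[0]

    def test_dangling_sphere_segment_flagged(self, planar_model):
        from dataclasses import replace

        bad = replace(planar_model, contact_spheres=(
            replace(planar_model.contact_spheres[0], segment="nowhere"),
            *planar_model.contact_spheres[1:]))
        violations = ls.validate_model(bad)
        assert len(violations) == 1 and "nowhere" in violations[0]


class TestScaleMuscleGroup:
    def test_identity(self, planar_model):
        same = ls.scale_muscle_group(planar_model, "quadriceps", 1.0)
        assert [m.F0 for m in same.muscles] == \
            [m.F0 for m in planar_model.muscles]

    @pytest.mark.parametrize("group, factor", [
        ("quadriceps", 1.35), ("hamstrings", 0.65)])
    def test_scales_only_the_group(self, planar_model, group, factor):
        scaled = ls.scale_muscle_group(planar_model, group, factor)
        for m0, m1 in zip(planar_model.muscles, scaled.muscles):
            expect = m0.F0 * factor if m0.group == group else m0.F0
            assert m1.F0 == pytest.approx(expect, rel=1e-15)

    def test_composable_inverse(self, model3d):
        back = ls.scale_muscle_group(
            ls.scale_muscle_group(model3d, "quadriceps", 1.35),
            "quadriceps", 1 / 1.35)
        for m0, m1 in zip(model3d.muscles, back.muscles):
            assert m1.F0 == pytest.approx(m0.F0, abs=1e-12 * m0.F0)

    def test_unknown_group_raises(self, planar_model):
        with pytest.raises(KeyError):
            ls.scale_muscle_group(planar_model, "wings", 2.0)


def test_lock_coordinates_roundtrip(model3d):
    locked = lock_coordinates(model3d, {"subtalar_l": 0.1})
    c = locked.coordinate("subtalar_l")
    assert c.locked and c.locked_value == pytest.approx(0.1)
    assert len(locked.coordinates) == 23   # still defined
    with pytest.raises(KeyError):
        lock_coordinates(model3d, {"flux_capacitor": 0.0})


def test_model_serialization_roundtrip(tmp_path, model3d):
    path = tmp_path / "model.yaml"
    save_model(model3d, path)
    back = load_model(path)
    assert back.coordinate_names == model3d.coordinate_names
    assert back.muscle_names == model3d.muscle_names
    for m0, m1 in zip(model3d.muscles, back.muscles):
        assert m1.F0 == m0.F0 and m1.l_slack == pytest.approx(m0.l_slack)
        assert m1.pulleys == m0.pulleys
    for s0, s1 in zip(model3d.segments, back.segments):
        np.testing.assert_allclose(s1.inertia, s0.inertia)
    assert ls.validate_model(back) == []
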