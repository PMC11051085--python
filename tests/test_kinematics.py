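"""Joint-angle geometry: leg lengths, law of cosines, feature assembly."""

import math

import numpy as np
import pytest

from gaitmatch.exceptions import ConfigurationError, DegenerateTriangleError
from gaitmatch.kinematics import (
    COCO_ANGLE_SET,
    MEDIAPIPE_ANGLE_SET,
    AngleDefinition,
    JointAngleSeries,
    TriangleLegs,
    angle_between,
    extract_angle_series,
    joint_angle,
    leg_lengths,
    load_angle_set,
    read_angle_csv,
    select_body_part,
    write_angle_csv,
)
from gaitmatch.synthetic import embed_angles_as_pose, sample_cohort, simulate_angle_series


def vector_angle_oracle(p, v, n):
    """Independent oracle: angle at v via the normalized dot product."""
    u1 = np.asarray(p, float) - v
    u2 = np.asarray(n, float) - v
    cosang = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
    return math.degrees(math.acos(np.clip(cosang, -1, 1)))


class TestLegLengths:
    def test_three_four_five(self):
        legs = leg_lengths((0, 0), (3, 4), (3, 0))
        assert legs.a == 5.0
        assert legs.b == 4.0
        assert legs.c == 3.0

    def test_right_isoceles(self):
        legs = leg_lengths((0, 1), (0, 0), (1, 0))
        assert legs.a == 1.0 and legs.b == 1.0
        assert legs.c == pytest.approx(math.sqrt(2))

    def test_3d_points(self):
        legs = leg_lengths((0, 0, 0), (1, 1, 1), (2, 2, 2))
        assert legs.a == pytest.approx(math.sqrt(3))
        assert legs.c == pytest.approx(2 * math.sqrt(3))

    def test_coincident_vertex_rejected(self):
        with pytest.raises(DegenerateTriangleError):
            leg_lengths((0, 0), (0, 0), (1, 0))
        with pytest.raises(DegenerateTriangleError):
            leg_lengths((1, 0), (0, 0), (0, 0))

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(DegenerateTriangleError):
            leg_lengths((0, 0), (1, 1, 1), (2, 2))


class TestJointAngle:
    @pytest.mark.parametrize("a,b,c,expected", [
        (1, 1, math.sqrt(2), 90.0),   # right angle
        (1, 1, 2, 180.0),             # collinear
        (1, 1, 1, 60.0),              # equilateral
        (1, 1, 0, 0.0),               # folded back
    ])
    def test_canonical_triangles(self, a, b, c, expected):
        assert joint_angle(TriangleLegs(a, b, c)) == pytest.approx(expected, abs=1e-9)

    def test_generic_triangle_against_dot_product(self):
        # a=2, b=3, c=2.5 -> arccos((4+9-6.25)/12); realize it as points
        angle = joint_angle(TriangleLegs(2, 3, 2.5))
        theta = math.acos((4 + 9 - 6.25) / 12.0)
        p = (2 * math.cos(theta), 2 * math.sin(theta))
        assert angle == pytest.approx(55.7711, abs=1e-3)
        assert angle == pytest.approx(vector_angle_oracle(p, (0, 0), (3, 0)), abs=1e-9)

    def test_matches_dot_product_oracle_on_random_triples(self, rng):
        for dim in (2, 3):
            pts = rng.normal(size=(1000, 3, dim))
            for p, v, n in pts:
                expected = vector_angle_oracle(p, v, n)
                assert angle_between(p, v, n) == pytest.approx(expected, abs=1e-9)

    def test_clamps_floating_point_excursion(self):
        # degenerate-ish legs can push the cosine epsilon above 1
        assert 0.0 <= joint_angle(TriangleLegs(1e-8, 1e-8, 2e-8)) <= 180.0


class TestAngleSets:
    def test_whole_body_has_ten_angles(self):
        assert len(MEDIAPIPE_ANGLE_SET) == 10

    def test_footless_set_has_six_angles(self):
        assert len(COCO_ANGLE_SET) == 6
        assert not any("Ankle" in d.name for d in COCO_ANGLE_SET)

    def test_duplicate_joint_in_triple_rejected(self):
        with pytest.raises(ConfigurationError):
            AngleDefinition("bad", "left_hip", "left_hip", "left_knee", "lower")

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        doc = [
            {"name": d.name, "proximal": d.proximal, "vertex": d.vertex,
             "distal": d.distal, "body_part": d.body_part}
            for d in MEDIAPIPE_ANGLE_SET
        ]
        path = tmp_path / "angles.yaml"
        path.write_text(yaml.safe_dump(doc))
        assert load_angle_set(path) == MEDIAPIPE_ANGLE_SET


class TestExtractAngleSeries:
    def test_column_count_and_order(self, small_cohort):
        pose = embed_angles_as_pose(simulate_angle_series(small_cohort[0], "0", n_frames=10))
        series = extract_angle_series(pose)
        assert series.values.shape == (10, 10)
        assert series.angle_names == [d.name for d in MEDIAPIPE_ANGLE_SET]

    def test_static_pose_gives_identical_rows(self, small_cohort):
        angles = simulate_angle_series(small_cohort[0], "0", n_frames=1)
        static = JointAngleSeries(
            values=np.repeat(angles.values, 5, axis=0), angle_names=angles.angle_names
        )
        series = extract_angle_series(embed_angles_as_pose(static))
        assert np.allclose(series.values, series.values[0], atol=1e-9)

    def test_rigid_and_scale_invariance(self, small_cohort, rng):
        """Rotation + translation + uniform scaling leaves angles unchanged."""
        pose = embed_angles_as_pose(simulate_angle_series(small_cohort[1], "0", n_frames=8))
        base = extract_angle_series(pose).values
        for _ in range(25):
            phi = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            scale = rng.uniform(0.1, 10)
            shift = rng.normal(size=2) * 100
            moved = pose
            moved = type(pose)(
                subject_id=pose.subject_id, view=pose.view, dialect=pose.dialect,
                joint_names=pose.joint_names,
                coords=scale * pose.coords @ R.T + shift,
                frame_index=pose.frame_index, visibility=pose.visibility,
            )
            assert np.allclose(extract_angle_series(moved).values, base, atol=1e-9)

    def test_degenerate_frame_dropped_with_warning(self, small_cohort, caplog):
        pose = embed_angles_as_pose(simulate_angle_series(small_cohort[0], "0", n_frames=6))
        pose.coords[2] = pose.coords[2, 0]  # collapse every joint onto one point
        with caplog.at_level("WARNING"):
            series = extract_angle_series(pose)
        assert series.n_frames == 5
        assert 2 not in list(series.frame_index)


class TestSelectBodyPart:
    def test_partition_of_whole_body(self, small_cohort):
        series = simulate_angle_series(small_cohort[0], "0", n_frames=12)
        upper = select_body_part(series, "upper")
        lower = select_body_part(series, "lower")
        whole = select_body_part(series, "whole")
        assert upper.angle_names == ["LElbow", "RElbow"]
        assert len(lower.angle_names) == 8
        assert set(upper.angle_names) | set(lower.angle_names) == set(whole.angle_names)
        assert not set(upper.angle_names) & set(lower.angle_names)
        assert whole.angle_names == series.angle_names

    def test_footless_lower_body_falls_back_to_four_angles(self):
        values = np.arange(12.0).reshape(2, 6)
        series = JointAngleSeries(values=values,
                                  angle_names=[d.name for d in COCO_ANGLE_SET])
        lower = select_body_part(series, "lower")
        assert lower.angle_names == ["LHip", "RHip", "LKnee", "RKnee"]

    def test_order_preserved(self, toy_series):
        sub = select_body_part(toy_series, "whole")
        assert sub.angle_names == ["A", "B", "C"]


def test_angle_csv_round_trip(tmp_path, small_cohort):
    series = simulate_angle_series(small_cohort[2], "36", n_frames=7, noise_sd=3.0, seed=4)
    path = tmp_path / "angles.csv"
    write_angle_csv(series, path)
    back = read_angle_csv(path)
    assert back.angle_names == series.angle_names
    assert np.array_equal(back.values, series.values)
    assert np.array_equal(back.frame_index, series.frame_index)
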