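"""Pose readers, canonical subsetting, cleaning and the CSV interchange."""

import json

import numpy as np
import pytest

from gaitmatch.exceptions import (
    AmbiguousFrameError,
    DegradedInputError,
    EmptyInputError,
    PoseParseError,
)
from gaitmatch.pose_io import (
    CANONICAL12_NAMES,
    CANONICAL16_NAMES,
    COCO18_NAMES,
    MEDIAPIPE33_NAMES,
    KeypointMap,
    PoseSequence,
    canonicalize,
    read_coco18,
    read_long_csv,
    read_mediapipe,
    write_long_csv,
)
from gaitmatch.synthetic import CohortConfig, sample_cohort, simulate_pose_sequence

from conftest import write_mediapipe_jsonl


def coco_frame(values, frame=0):
    return {"frame": frame, "people": [{"pose_keypoints_2d": values}]}


class TestReadMediapipe:
    def test_single_frame(self, tmp_path, rng):
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, rng.normal(size=(1, 33, 3)))
        seq = read_mediapipe(path)
        assert seq.n_frames == 1
        assert seq.n_joints == 33
        assert seq.dialect == "mediapipe33"
        assert seq.has_z

    def test_frame_order_preserved(self, tmp_path, rng):
        path = tmp_path / "seq.jsonl"
        coords = rng.normal(size=(10, 33, 3))
        write_mediapipe_jsonl(path, coords)
        seq = read_mediapipe(path)
        assert seq.n_frames == 10
        assert list(seq.frame_index) == list(range(10))
        assert np.array_equal(seq.coords, coords)

    def test_missing_landmark_names_frame(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        rec = {"frame": 3, "landmarks": [{"x": 0, "y": 0, "z": 0}] * 32}
        path.write_text(json.dumps(rec) + "\n")
        with pytest.raises(PoseParseError, match="frame 3"):
            read_mediapipe(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_mediapipe(path)


class TestReadCoco18:
    def test_single_person_frame(self, tmp_path, rng):
        vals = rng.normal(size=54).tolist()
        path = tmp_path / "seq.json"
        path.write_text(json.dumps([coco_frame(vals)]))
        seq = read_coco18(path)
        assert seq.n_frames == 1
        assert seq.n_joints == 18
        assert not seq.has_z
        # confidence lands in visibility
        assert seq.visibility[0, 0] == pytest.approx(vals[2])

    def test_empty_people_frame_dropped(self, tmp_path, rng, caplog):
        vals = rng.normal(size=54).tolist()
        frames = [coco_frame(vals, 0), {"frame": 1, "people": []}, coco_frame(vals, 2)]
        path = tmp_path / "seq.json"
        path.write_text(json.dumps(frames))
        with caplog.at_level("WARNING"):
            seq = read_coco18(path)
        assert seq.n_frames == 2
        assert list(seq.frame_index) == [0, 2]

    def test_two_people_rejected(self, tmp_path, rng):
        vals = rng.normal(size=54).tolist()
        rec = {"frame": 0, "people": [{"pose_keypoints_2d": vals}] * 2}
        path = tmp_path / "seq.json"
        path.write_text(json.dumps([rec]))
        with pytest.raises(AmbiguousFrameError):
            read_coco18(path)


class TestCanonicalize:
    def test_mediapipe_33_to_16(self, tmp_path, rng):
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, rng.normal(size=(5, 33, 3)),
                              visibility=np.ones((5, 33)))
        seq = read_mediapipe(path)
        out, report = canonicalize(seq)
        assert out.dialect == "canonical16"
        assert out.joint_names == CANONICAL16_NAMES
        assert out.n_joints == 16
        assert report.n_kept_frames == 5

    def test_coco_18_to_12_without_feet(self, tmp_path, rng):
        vals = rng.normal(size=(2, 54))
        vals[:, 2::3] = 1.0  # all confident
        frames = [coco_frame(v.tolist(), i) for i, v in enumerate(vals)]
        path = tmp_path / "seq.json"
        path.write_text(json.dumps(frames))
        out, _ = canonicalize(read_coco18(path))
        assert out.dialect == "canonical12"
        assert out.joint_names == CANONICAL12_NAMES
        assert not any("heel" in n or "foot" in n for n in out.joint_names)

    def test_low_visibility_frame_dropped(self, tmp_path, rng):
        vis = np.ones((4, 33))
        vis[2, MEDIAPIPE33_NAMES.index("left_wrist")] = 0.0
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, rng.normal(size=(4, 33, 3)), visibility=vis)
        out, report = canonicalize(read_mediapipe(path), min_visibility=0.5)
        assert out.n_frames == 3
        assert report.dropped_frames == (2,)
        assert 2 not in list(out.frame_index)

    def test_surviving_coordinates_untouched_and_order_kept(self, tmp_path, rng):
        coords = rng.normal(size=(6, 33, 3))
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, coords, visibility=np.ones((6, 33)))
        out, _ = canonicalize(read_mediapipe(path))
        wrist = out.joint_coords("left_wrist")
        assert np.array_equal(wrist, coords[:, MEDIAPIPE33_NAMES.index("left_wrist"), :])
        assert np.all(np.diff(out.frame_index) > 0)

    def test_degraded_input_rejected(self, tmp_path, rng):
        vis = np.ones((10, 33))
        vis[:6, MEDIAPIPE33_NAMES.index("right_knee")] = 0.1  # 60% of frames bad
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, rng.normal(size=(10, 33, 3)), visibility=vis)
        with pytest.raises(DegradedInputError):
            canonicalize(read_mediapipe(path))

    def test_wrong_dialect_map_rejected(self, tmp_path, rng):
        path = tmp_path / "seq.jsonl"
        write_mediapipe_jsonl(path, rng.normal(size=(2, 33, 3)))
        bad_map = KeypointMap("coco18", {n: n for n in CANONICAL12_NAMES})
        with pytest.raises(PoseParseError):
            canonicalize(read_mediapipe(path), keypoint_map=bad_map)


class TestKeypointMaps:
    def test_canonical16_has_sixteen_entries(self):
        from gaitmatch.pose_io import MEDIAPIPE33_TO_CANONICAL

        assert len(MEDIAPIPE33_TO_CANONICAL.mapping) == 16

    def test_coco_map_has_no_foot_entries(self):
        from gaitmatch.pose_io import COCO18_TO_CANONICAL

        assert len(COCO18_TO_CANONICAL.mapping) == 12
        assert not any("heel" in n or "foot" in n for n in COCO18_TO_CANONICAL.mapping)
        assert set(COCO18_TO_CANONICAL.mapping) <= set(COCO18_NAMES) | set(CANONICAL12_NAMES)


class TestInterchangeCSV:
    def test_round_trip_bit_exact(self, tmp_path):
        params = sample_cohort(CohortConfig(n_subjects=1), 5)[0]
        pose = simulate_pose_sequence(params, "54", seed=8, n_frames=7, jitter_sd=0.01)
        path = tmp_path / "pose.csv"
        write_long_csv(pose, path)
        back = read_long_csv(path, subject_id=pose.subject_id, view=pose.view)
        assert back.joint_names == pose.joint_names
        assert np.array_equal(back.coords, pose.coords)  # bit-exact
        assert np.array_equal(back.frame_index, pose.frame_index)

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,joint,x,y\n0,left_hip,1.0,2.0\n1,left_hip,1.0,2.0\n"
                        "0,right_hip,3.0,4.0\n")
        with pytest.raises(PoseParseError):
            read_long_csv(path)

    def test_strictly_increasing_frames_enforced(self):
        with pytest.raises(PoseParseError):
            PoseSequence(subject_id="x", view="0", dialect="canonical16",
                         joint_names=CANONICAL16_NAMES,
                         coords=np.zeros((2, 16, 2)), frame_index=np.array([3, 3]))
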