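"""Reading and canonicalizing pose-estimation output.

Upstream pose estimators emit landmarks in different *dialects*:

* ``mediapipe33`` — 33 named body landmarks with x, y, z and a visibility
  score (MediaPipe Pose).
* ``coco18`` — 18 keypoints with x, y and a detection confidence
  (OpenPose / AlphaPose COCO output; no foot landmarks).
* ``canonical16`` / ``canonical12`` — the package's internal dialects: the
  16 limb keypoints the joint-angle extraction needs (shoulders, elbows,
  wrists, hips, knees, ankles, heels, foot tips, left and right), or the
  12-keypoint subset available when the source has no feet.

All readers return a :class:`PoseSequence`; :func:`canonicalize` maps a
dialect sequence onto the canonical keypoints and drops frames whose
required keypoints are missing or below a visibility threshold.
Coordinates are kept exactly as read — every downstream angle is invariant
to translation, rotation and uniform scaling, so pixel vs. normalized
units never matter.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    AmbiguousFrameError,
    DegradedInputError,
    EmptyInputError,
    PoseParseError,
)

logger = logging.getLogger(__name__)

# MediaPipe Pose landmark names, index 0..32.
MEDIAPIPE33_NAMES = [
    "nose", "left_eye_inner", "left_eye", "left_eye_outer", "right_eye_inner",
    "right_eye", "right_eye_outer", "left_ear", "right_ear", "mouth_left",
    "mouth_right", "left_shoulder", "right_shoulder", "left_elbow",
    "right_elbow", "left_wrist", "right_wrist", "left_pinky", "right_pinky",
    "left_index", "right_index", "left_thumb", "right_thumb", "left_hip",
    "right_hip", "left_knee", "right_knee", "left_ankle", "right_ankle",
    "left_heel", "right_heel", "left_foot_index", "right_foot_index",
]

# OpenPose/AlphaPose COCO-18 keypoint names, index 0..17.
COCO18_NAMES = [
    "nose", "neck", "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist", "right_hip", "right_knee",
    "right_ankle", "left_hip", "left_knee", "left_ankle", "right_eye",
    "left_eye", "right_ear", "left_ear",
]

# The 16 canonical keypoints: the minimal landmark set supporting all ten
# elbow/hip/knee/ankle(front, back) angles on both sides.
CANONICAL16_NAMES = [
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
    "left_heel", "right_heel", "left_foot_index", "right_foot_index",
]

# COCO sources carry no heel / foot-tip landmarks: 12 canonical keypoints.
CANONICAL12_NAMES = CANONICAL16_NAMES[:12]


@dataclass(frozen=True)
class KeypointMap:
    """Mapping from a dialect's joint labels to canonical joint names."""

    dialect: str
    mapping: Mapping[str, str]  # dialect joint name -> canonical name

    @property
    def canonical_names(self) -> list[str]:
        target = CANONICAL16_NAMES if len(self.mapping) == 16 else CANONICAL12_NAMES
        return [n for n in target if n in set(self.mapping.values())]


MEDIAPIPE33_TO_CANONICAL = KeypointMap(
    dialect="mediapipe33",
    mapping={name: name for name in CANONICAL16_NAMES},
)

COCO18_TO_CANONICAL = KeypointMap(
    dialect="coco18",
    mapping={name: name for name in CANONICAL12_NAMES},
)

_DEFAULT_MAPS = {
    "mediapipe33": MEDIAPIPE33_TO_CANONICAL,
    "coco18": COCO18_TO_CANONICAL,
}


@dataclass
class PoseSequence:
    """One person's landmark time series in one camera view.

    ``coords`` has shape (T, J, C) with C = 2 or 3; ``visibility`` (T, J)
    is in [0, 1] where available (COCO confidence is stored here).
    """

    subject_id: str
    view: str
    dialect: str
    joint_names: list[str]
    coords: np.ndarray
    frame_index: np.ndarray
    visibility: np.ndarray | None = None
    _name_to_col: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.coords.ndim != 3:
            raise PoseParseError("coords must have shape (frames, joints, dims)")
        if self.coords.shape[0] != self.frame_index.shape[0]:
            raise PoseParseError("frame_index length must match coords")
        if self.frame_index.size > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise PoseParseError("frame indices must be strictly increasing")
        self._name_to_col = {n: i for i, n in enumerate(self.joint_names)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def has_z(self) -> bool:
        return self.coords.shape[2] == 3

    def joint_column(self, name: str) -> int:
        try:
            return self._name_to_col[name]
        except KeyError:
            raise KeyError(f"joint {name!r} not in dialect {self.dialect!r}") from None

    def joint_coords(self, name: str) -> np.ndarray:
        """(T, C) coordinates of one named joint."""
        return self.coords[:, self.joint_column(name), :]


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of :func:`canonicalize` frame filtering."""

    n_input_frames: int
    n_kept_frames: int
    dropped_frames: tuple[int, ...]

    @property
    def fraction_dropped(self) -> float:
        if self.n_input_frames == 0:
            return 0.0
        return 1.0 - self.n_kept_frames / self.n_input_frames


def read_mediapipe(path: str | Path, subject_id: str = "", view: str = "") -> PoseSequence:
    """Read a MediaPipe 33-landmark sequence from JSON-lines.

    Each line is one frame: ``{"frame": t, "landmarks": [{"x":..,"y":..,
    "z":..,"visibility":..}, ...33 entries]}``. Coordinates are taken as
    given; no transformation is applied.
    """
    path = Path(path)
    coords, vis, frames = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise PoseParseError(f"frame record {lineno}: invalid JSON ({exc})") from exc
            frame_idx = rec.get("frame", lineno)
            landmarks = rec.get("landmarks")
            if landmarks is None or len(landmarks) != 33:
                got = 0 if landmarks is None else len(landmarks)
                raise PoseParseError(
                    f"frame {frame_idx}: expected 33 landmarks, got {got}"
                )
            try:
                xyz = [(lm["x"], lm["y"], lm.get("z", 0.0)) for lm in landmarks]
                v = [float(lm.get("visibility", 1.0)) for lm in landmarks]
            except (KeyError, TypeError) as exc:
                raise PoseParseError(f"frame {frame_idx}: malformed landmark ({exc})") from exc
            coords.append(xyz)
            vis.append(v)
            frames.append(int(frame_idx))
    if not coords:
        raise EmptyInputError(f"{path}: no frames")
    return PoseSequence(
        subject_id=subject_id,
        view=view,
        dialect="mediapipe33",
        joint_names=list(MEDIAPIPE33_NAMES),
        coords=np.asarray(coords, dtype=float),
        frame_index=np.asarray(frames),
        visibility=np.asarray(vis, dtype=float),
    )


def read_coco18(path: str | Path, subject_id: str = "", view: str = "") -> PoseSequence:
    """Read an OpenPose/AlphaPose COCO-18 sequence from a JSON file.

    The file holds a list of frame objects (or ``{"frames": [...]}``), each
    with ``people`` carrying a flat ``pose_keypoints_2d`` array of
    18 × (x, y, confidence). The method assumes a single walker: frames
    with several people raise; frames with none are dropped with a warning.
    """
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    if isinstance(doc, dict):
        doc = doc.get("frames", [])
    coords, vis, frames = [], [], []
    for rec_no, rec in enumerate(doc):
        frame_idx = int(rec.get("frame", rec_no))
        people = rec.get("people", [])
        if len(people) > 1:
            raise AmbiguousFrameError(
                f"frame {frame_idx}: {len(people)} people detected; "
                "the matching method assumes a single walker"
            )
        if not people:
            logger.warning("%s: frame %d has no detected person; dropped", path, frame_idx)
            continue
        flat = people[0].get("pose_keypoints_2d")
        if flat is None or len(flat) != 54:
            got = 0 if flat is None else len(flat)
            raise PoseParseError(
                f"frame {frame_idx}: expected 54 values in pose_keypoints_2d, got {got}"
            )
        arr = np.asarray(flat, dtype=float).reshape(18, 3)
        coords.append(arr[:, :2])
        vis.append(arr[:, 2])
        frames.append(frame_idx)
    if not coords:
        raise EmptyInputError(f"{path}: no frames with a detected person")
    return PoseSequence(
        subject_id=subject_id,
        view=view,
        dialect="coco18",
        joint_names=list(COCO18_NAMES),
        coords=np.asarray(coords, dtype=float),
        frame_index=np.asarray(frames),
        visibility=np.asarray(vis, dtype=float),
    )


def read_long_csv(path: str | Path, subject_id: str = "", view: str = "",
                  dialect: str | None = None) -> PoseSequence:
    """Read the generic long-format CSV: ``frame,joint,x,y[,z][,visibility]``.

    ``joint`` holds canonical joint names; the dialect is inferred from the
    joint set (canonical16 / canonical12) unless given explicitly.
    """
    path = Path(path)
    rows: dict[int, dict[str, tuple]] = {}
    has_z = has_vis = False
    with path.open() as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty file")
        cols = set(reader.fieldnames)
        if not {"frame", "joint", "x", "y"} <= cols:
            raise PoseParseError(f"{path}: need columns frame,joint,x,y")
        has_z = "z" in cols
        has_vis = "visibility" in cols
        for row in reader:
            try:
                t = int(row["frame"])
                xyz = (float(row["x"]), float(row["y"])) + (
                    (float(row["z"]),) if has_z else ()
                )
                v = float(row["visibility"]) if has_vis else 1.0
            except (TypeError, ValueError) as exc:
                raise PoseParseError(f"frame {row.get('frame')}: bad value ({exc})") from exc
            rows.setdefault(t, {})[row["joint"]] = (xyz, v)
    if not rows:
        raise EmptyInputError(f"{path}: no frames")
    frames = sorted(rows)
    joint_names = sorted({j for r in rows.values() for j in r})
    # keep canonical ordering when the joint set matches a known dialect
    for ref in (CANONICAL16_NAMES, CANONICAL12_NAMES):
        if set(joint_names) == set(ref):
            joint_names = list(ref)
            break
    ndim = 3 if has_z else 2
    coords = np.full((len(frames), len(joint_names), ndim), np.nan)
    vis = np.zeros((len(frames), len(joint_names)))
    for ti, t in enumerate(frames):
        for ji, j in enumerate(joint_names):
            if j in rows[t]:
                xyz, v = rows[t][j]
                coords[ti, ji, :] = xyz
                vis[ti, ji] = v
    if np.isnan(coords).any():
        missing = int(np.isnan(coords[..., 0]).sum())
        raise PoseParseError(f"{path}: {missing} (frame, joint) cells missing")
    if dialect is None:
        dialect = {16: "canonical16", 12: "canonical12"}.get(len(joint_names), "generic")
    return PoseSequence(
        subject_id=subject_id, view=view, dialect=dialect,
        joint_names=joint_names, coords=coords,
        frame_index=np.asarray(frames), visibility=vis if has_vis else None,
    )


def write_long_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write the interchange CSV (``frame,joint,x,y[,z][,visibility]``).

    Coordinates are written with ``repr`` round-trip precision so a
    write/read cycle reproduces them bit-exactly.
    """
    path = Path(path)
    header = ["frame", "joint", "x", "y"]
    if seq.has_z:
        header.append("z")
    if seq.visibility is not None:
        header.append("visibility")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for ti, t in enumerate(seq.frame_index):
            for ji, name in enumerate(seq.joint_names):
                row = [int(t), name] + [repr(float(c)) for c in seq.coords[ti, ji]]
                if seq.visibility is not None:
                    row.append(repr(float(seq.visibility[ti, ji])))
                writer.writerow(row)


def canonicalize(
    seq: PoseSequence,
    keypoint_map: KeypointMap | None = None,
    min_visibility: float = 0.5,
    max_drop_fraction: float = 0.5,
) -> tuple[PoseSequence, CleaningReport]:
    """Subset a dialect sequence to the canonical keypoints and clean frames.

    Frames in which any required keypoint falls below ``min_visibility``
    are dropped (never interpolated — DTW tolerates unequal lengths).
    Raises :class:`DegradedInputError` when more than ``max_drop_fraction``
    of the frames are lost.
    """
    if keypoint_map is None:
        if seq.dialect in ("canonical16", "canonical12"):
            keypoint_map = KeypointMap(seq.dialect, {n: n for n in seq.joint_names})
        else:
            try:
                keypoint_map = _DEFAULT_MAPS[seq.dialect]
            except KeyError:
                raise PoseParseError(f"no default keypoint map for dialect {seq.dialect!r}")
    if keypoint_map.dialect != seq.dialect:
        raise PoseParseError(
            f"keypoint map is for {keypoint_map.dialect!r}, sequence is {seq.dialect!r}"
        )
    src_names = list(keypoint_map.mapping)
    out_names = keypoint_map.canonical_names
    canon_to_src = {keypoint_map.mapping[s]: s for s in src_names}
    cols = [seq.joint_column(canon_to_src[n]) for n in out_names]

    coords = seq.coords[:, cols, :]
    vis = seq.visibility[:, cols] if seq.visibility is not None else None
    if vis is not None:
        keep = np.all(vis >= min_visibility, axis=1)
    else:
        keep = np.ones(seq.n_frames, dtype=bool)
    dropped = tuple(int(t) for t in seq.frame_index[~keep])
    report = CleaningReport(
        n_input_frames=seq.n_frames,
        n_kept_frames=int(keep.sum()),
        dropped_frames=dropped,
    )
    if seq.n_frames and report.fraction_dropped > max_drop_fraction:
        raise DegradedInputError(
            f"{report.n_input_frames - report.n_kept_frames} of "
            f"{report.n_input_frames} frames below visibility "
            f"{min_visibility}; sequence too degraded to match"
        )
    if dropped:
        logger.warning(
            "canonicalize: dropped %d/%d frames below visibility %.2f",
            len(dropped), seq.n_frames, min_visibility,
        )
    out_dialect = "canonical16" if len(out_names) == 16 else "canonical12"
    out = PoseSequence(
        subject_id=seq.subject_id,
        view=seq.view,
        dialect=out_dialect,
        joint_names=out_names,
        coords=coords[keep],
        frame_index=seq.frame_index[keep],
        visibility=vis[keep] if vis is not None else None,
    )
    return out, report
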