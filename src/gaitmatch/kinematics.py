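"""Joint angles from landmark triples.

Each angle is the interior angle at a *vertex* joint between two adjacent
body segments. For a triple (proximal, vertex, distal) the three triangle
legs are Euclidean distances

    a = |vertex - proximal|,  b = |vertex - distal|,  c = |proximal - distal|

and the vertex angle follows from the law of cosines,

    theta = arccos((a^2 + b^2 - c^2) / (2 a b)),

reported in degrees, always in [0, 180]. The construction uses z when the
landmarks carry it and works identically in 2D.

The default whole-body set has ten angles — elbows, hips, knees and ankle
front (toward the foot tip) / ankle back (toward the heel), left and
right. Sources without foot landmarks (COCO-18) support the six-angle
subset (elbows, hips, knees). Feature vectors are split into body parts:
upper = the two elbow angles, lower = everything else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

from .exceptions import ConfigurationError, DegenerateTriangleError
from .pose_io import PoseSequence

logger = logging.getLogger(__name__)

BodyPart = Literal["whole", "upper", "lower"]


@dataclass(frozen=True)
class TriangleLegs:
    """Euclidean side lengths of the joint triangle at one frame."""

    a: float  # vertex -> proximal
    b: float  # vertex -> distal
    c: float  # proximal -> distal

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise DegenerateTriangleError(
                f"legs touching the vertex must be positive (a={self.a}, b={self.b})"
            )
        if self.c < 0:
            raise DegenerateTriangleError(f"leg c cannot be negative (c={self.c})")


@dataclass(frozen=True)
class AngleDefinition:
    """One named joint angle: the interior angle at ``vertex``."""

    name: str
    proximal: str
    vertex: str
    distal: str
    body_part: Literal["upper", "lower"]

    def __post_init__(self) -> None:
        if len({self.proximal, self.vertex, self.distal}) != 3:
            raise ConfigurationError(f"angle {self.name}: joints must be distinct")


def _angles(defs: Iterable[tuple[str, str, str, str, str]]) -> tuple[AngleDefinition, ...]:
    return tuple(AngleDefinition(*d) for d in defs)


#: Ten-angle whole-body set (column order is fixed throughout the package).
MEDIAPIPE_ANGLE_SET: tuple[AngleDefinition, ...] = _angles([
    ("LElbow", "left_shoulder", "left_elbow", "left_wrist", "upper"),
    ("RElbow", "right_shoulder", "right_elbow", "right_wrist", "upper"),
    ("LHip", "left_shoulder", "left_hip", "left_knee", "lower"),
    ("RHip", "right_shoulder", "right_hip", "right_knee", "lower"),
    ("LKnee", "left_hip", "left_knee", "left_ankle", "lower"),
    ("RKnee", "right_hip", "right_knee", "right_ankle", "lower"),
    ("LAnkleFront", "left_knee", "left_ankle", "left_foot_index", "lower"),
    ("RAnkleFront", "right_knee", "right_ankle", "right_foot_index", "lower"),
    ("LAnkleBack", "left_knee", "left_ankle", "left_heel", "lower"),
    ("RAnkleBack", "right_knee", "right_ankle", "right_heel", "lower"),
])

#: Six-angle set for sources without foot landmarks (no ankle angles).
COCO_ANGLE_SET: tuple[AngleDefinition, ...] = MEDIAPIPE_ANGLE_SET[:6]

ANGLE_SETS = {"mediapipe": MEDIAPIPE_ANGLE_SET, "coco": COCO_ANGLE_SET}

_DIALECT_ANGLE_SETS = {
    "canonical16": MEDIAPIPE_ANGLE_SET,
    "mediapipe33": MEDIAPIPE_ANGLE_SET,
    "canonical12": COCO_ANGLE_SET,
    "coco18": COCO_ANGLE_SET,
}


@dataclass
class JointAngleSeries:
    """T × J matrix of joint angles in degrees with fixed column order."""

    values: np.ndarray
    angle_names: list[str]
    subject_id: str = ""
    view: str = ""
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.angle_names):
            raise ConfigurationError("values must be (frames, len(angle_names))")
        if self.frame_index is None:
            self.frame_index = np.arange(self.values.shape[0])

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.angle_names.index(name)]


def leg_lengths(p_prev: Sequence[float], p_vertex: Sequence[float],
                p_next: Sequence[float]) -> TriangleLegs:
    """Euclidean legs of the triangle (proximal, vertex, distal)."""
    p_prev = np.asarray(p_prev, dtype=float)
    p_vertex = np.asarray(p_vertex, dtype=float)
    p_next = np.asarray(p_next, dtype=float)
    if not (p_prev.shape == p_vertex.shape == p_next.shape):
        raise DegenerateTriangleError("points must share dimensionality")
    a = float(np.linalg.norm(p_vertex - p_prev))
    b = float(np.linalg.norm(p_vertex - p_next))
    c = float(np.linalg.norm(p_prev - p_next))
    if a == 0.0 or b == 0.0:
        raise DegenerateTriangleError("vertex coincides with an endpoint")
    return TriangleLegs(a=a, b=b, c=c)


def joint_angle(legs: TriangleLegs) -> float:
    """Vertex angle in degrees via the law of cosines.

    The arccos argument is clamped to [-1, 1] to absorb floating-point
    excursions on near-collinear triples.
    """
    cos_theta = (legs.a**2 + legs.b**2 - legs.c**2) / (2.0 * legs.a * legs.b)
    return math.degrees(math.acos(min(1.0, max(-1.0, cos_theta))))


def angle_between(p_prev, p_vertex, p_next) -> float:
    """Convenience: angle at ``p_vertex`` in degrees from three points."""
    return joint_angle(leg_lengths(p_prev, p_vertex, p_next))


def extract_angle_series(
    seq: PoseSequence,
    angle_set: Sequence[AngleDefinition] | None = None,
) -> JointAngleSeries:
    """Compute the angle matrix for a canonical pose sequence.

    Frames in which any angle's triple is degenerate (vertex coinciding
    with an endpoint) are dropped with a warning, consistent with the
    drop-don't-interpolate cleaning policy.
    """
    if angle_set is None:
        angle_set = _DIALECT_ANGLE_SETS.get(seq.dialect)
        if angle_set is None:
            raise ConfigurationError(
                f"no default angle set for dialect {seq.dialect!r}; pass one explicitly"
            )
    names = [d.name for d in angle_set]
    if len(set(names)) != len(names):
        raise ConfigurationError("angle names must be unique")

    T = seq.n_frames
    values = np.empty((T, len(angle_set)))
    ok = np.ones(T, dtype=bool)
    for j, d in enumerate(angle_set):
        p = seq.joint_coords(d.proximal)
        v = seq.joint_coords(d.vertex)
        n = seq.joint_coords(d.distal)
        a = np.linalg.norm(v - p, axis=1)
        b = np.linalg.norm(v - n, axis=1)
        c = np.linalg.norm(p - n, axis=1)
        degen = (a == 0.0) | (b == 0.0)
        ok &= ~degen
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_theta = (a**2 + b**2 - c**2) / (2.0 * a * b)
        values[:, j] = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    if not ok.all():
        logger.warning(
            "extract_angle_series: dropped %d frame(s) with degenerate joint triples",
            int((~ok).sum()),
        )
    frame_index = seq.frame_index[ok] if seq.frame_index is not None else None
    return JointAngleSeries(
        values=values[ok],
        angle_names=names,
        subject_id=seq.subject_id,
        view=seq.view,
        frame_index=frame_index,
    )


UPPER_ANGLES = ("LElbow", "RElbow")


def select_body_part(series: JointAngleSeries, part: BodyPart) -> JointAngleSeries:
    """Column subset for a body part, preserving column order.

    upper = the elbow angles; lower = all remaining angles; whole = all.
    Requested columns missing from the series (e.g. ankle angles on
    COCO-18 data) are skipped with a warning.
    """
    if part == "whole":
        wanted = list(series.angle_names)
    elif part == "upper":
        wanted = [n for n in UPPER_ANGLES]
    elif part == "lower":
        wanted = [n for n in series.angle_names if n not in UPPER_ANGLES]
    else:
        raise ConfigurationError(f"unknown body part {part!r}")
    available = [n for n in series.angle_names if n in wanted]
    missing = [n for n in wanted if n not in series.angle_names]
    if missing:
        logger.warning("select_body_part(%s): angles %s unavailable; using %s",
                       part, missing, available)
    if not available:
        raise ConfigurationError(f"no {part!r}-body angles present in series")
    cols = [series.angle_names.index(n) for n in available]
    return JointAngleSeries(
        values=series.values[:, cols],
        angle_names=available,
        subject_id=series.subject_id,
        view=series.view,
        frame_index=series.frame_index,
    )


def load_angle_set(path: str | Path) -> tuple[AngleDefinition, ...]:
    """Load an angle set from YAML: a list of {name, proximal, vertex,
    distal, body_part} entries."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list) or not doc:
        raise ConfigurationError(f"{path}: expected a non-empty list of angle entries")
    return _angles([
        (e["name"], e["proximal"], e["vertex"], e["distal"], e["body_part"])
        for e in doc
    ])


def write_angle_csv(series: JointAngleSeries, path: str | Path) -> None:
    """One row per frame: frame index plus one column per angle."""
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", *series.angle_names])
        for t, row in zip(series.frame_index, series.values):
            writer.writerow([int(t), *(repr(float(x)) for x in row)])


def read_angle_csv(path: str | Path, subject_id: str = "", view: str = "") -> JointAngleSeries:
    """Inverse of :func:`write_angle_csv`."""
    import csv

    with Path(path).open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "frame":
            raise ConfigurationError(f"{path}: not an angle CSV (no 'frame' column)")
        names = header[1:]
        frames, rows = [], []
        for row in reader:
            frames.append(int(row[0]))
            rows.append([float(x) for x in row[1:]])
    return JointAngleSeries(
        values=np.asarray(rows, dtype=float).reshape(len(rows), len(names)),
        angle_names=names,
        subject_id=subject_id,
        view=view,
        frame_index=np.asarray(frames),
    )
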