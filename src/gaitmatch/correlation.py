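"""Spearman rank correlation between joint-angle columns.

The correlation feature condenses a T × J angle series into a J × J
matrix that is independent of frame order up to monotone re-timing: each
column is replaced by its ascending fractional ranks (tied values all
receive the arithmetic mean of the integer ranks they span), and the
correlation between two columns is the Pearson correlation of the rank
vectors, computed in expectation form

    rho = (E[XY] - E[X] E[Y]) / (sqrt(E[X^2] - E[X]^2) sqrt(E[Y^2] - E[Y]^2))

with expectations taken as arithmetic means over the T frames. Because a
walker's joints move together, the off-diagonal structure of this matrix
is characteristic of the person and serves as a frame-independent
matching feature alongside the raw angle series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, ShapeMismatchError
from .kinematics import JointAngleSeries

logger = logging.getLogger(__name__)

#: Correlation assigned to any pair involving a zero-variance (constant)
#: column, where the denominator vanishes: 0 encodes "no monotone
#: relationship" without poisoning downstream distances.
DEGENERATE_CORRELATION = 0.0


@dataclass(frozen=True)
class RankVector:
    """Ascending fractional ranks of one column's T values."""

    ranks: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=float))


@dataclass
class CorrelationFeature:
    """Symmetric J × J Spearman matrix over the angle columns."""

    matrix: np.ndarray
    angle_names: list[str]
    subject_id: str = ""
    view: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        J = len(self.angle_names)
        if self.matrix.shape != (J, J):
            raise ShapeMismatchError("matrix must be J x J for J angle names")

    @property
    def n_angles(self) -> int:
        return len(self.angle_names)


def rank_with_ties(values) -> RankVector:
    """Ascending fractional ranks (1-based); tied runs share the mean rank.

    The minimum value receives rank 1. A run of m equal values occupying
    integer ranks r..r+m-1 all receive (r + r+m-1) / 2, so the total rank
    mass T(T+1)/2 is conserved.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ShapeMismatchError("rank_with_ties expects a 1-D sequence")
    T = values.size
    if T < 2:
        raise InsufficientDataError(f"need at least 2 values to rank, got {T}")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(T, dtype=float)
    i = 0
    while i < T:
        j = i
        while j + 1 < T and values[order[j + 1]] == values[order[i]]:
            j += 1
        # sorted positions i..j (0-based) -> integer ranks i+1..j+1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return RankVector(ranks=ranks)


def spearman_pair(x, y, degenerate_value: float = DEGENERATE_CORRELATION) -> float:
    """Spearman correlation of two equal-length columns, in [-1, 1].

    Returns ``degenerate_value`` (with a warning) when either column is
    constant, since the rank variance — the denominator — is then zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeMismatchError(f"length mismatch: {x.shape} vs {y.shape}")
    rx = rank_with_ties(x).ranks
    ry = rank_with_ties(y).ranks
    return _rank_pearson(rx, ry, degenerate_value)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray, degenerate_value: float) -> float:
    ex, ey = rx.mean(), ry.mean()
    var_x = (rx**2).mean() - ex**2
    var_y = (ry**2).mean() - ey**2
    if var_x <= 0.0 or var_y <= 0.0:
        logger.warning("spearman: zero-variance column; correlation set to %s",
                       degenerate_value)
        return degenerate_value
    rho = ((rx * ry).mean() - ex * ey) / np.sqrt(var_x * var_y)
    return float(np.clip(rho, -1.0, 1.0))


def correlation_matrix(
    series: JointAngleSeries,
    degenerate_value: float = DEGENERATE_CORRELATION,
) -> CorrelationFeature:
    """J × J Spearman matrix over all column pairs of an angle series.

    Computed once over the full sequence; the upper triangle is mirrored,
    so the result is exactly symmetric. The diagonal is 1 for every
    non-constant column and ``degenerate_value`` for constant ones.
    """
    T, J = series.values.shape
    if T < 2:
        raise InsufficientDataError(f"need at least 2 frames, got {T}")
    if J < 2:
        raise InsufficientDataError(f"need at least 2 angle columns, got {J}")
    ranks = np.column_stack([rank_with_ties(series.values[:, j]).ranks
                             for j in range(J)])
    mat = np.empty((J, J))
    for u in range(J):
        for v in range(u, J):
            mat[u, v] = _rank_pearson(ranks[:, u], ranks[:, v], degenerate_value)
            mat[v, u] = mat[u, v]
    return CorrelationFeature(
        matrix=mat,
        angle_names=list(series.angle_names),
        subject_id=series.subject_id,
        view=series.view,
    )


def write_correlation_json(feature: CorrelationFeature, path) -> None:
    """Persist a correlation feature as JSON."""
    import json
    from pathlib import Path

    doc = {
        "subject": feature.subject_id,
        "view": feature.view,
        "angle_names": feature.angle_names,
        "matrix": feature.matrix.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def write_correlation_csv(feature: CorrelationFeature, path) -> None:
    """Square CSV with angle names as both header row and first column."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["", *feature.angle_names])
        for name, row in zip(feature.angle_names, feature.matrix):
            writer.writerow([name, *(repr(float(x)) for x in row)])
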