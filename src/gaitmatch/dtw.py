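"""Dependent multi-dimensional Dynamic Time Warping (DTW_D).

Two feature matrices A (T1 × J) and B (T2 × J) are aligned by a monotone,
continuous warping path. The local cost between frame u of A and frame v
of B is the Euclidean norm of the difference across all J dimensions —
the "dependent" variant, which warps all dimensions on a single shared
time axis rather than aligning each dimension independently. The DTW
distance is the minimum accumulated local cost over all admissible paths,
found by the classic dynamic program

    D(u, v) = cost(u, v) + min{D(u-1, v), D(u, v-1), D(u-1, v-1)}

with the symmetric three-way step pattern, unit weights, no windowing and
no path-length normalization: distances are only ever compared within one
view, so any monotone normalization would not change the argmin.

Both feature kinds ride through the same machinery: an angle series is a
sequence of T frames (J-dimensional vectors), and a J × J correlation
matrix is treated as a sequence of its J rows in the fixed angle order.

The inner accumulation loop is JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .correlation import CorrelationFeature
from .exceptions import ConfigurationError, InsufficientDataError, ShapeMismatchError
from .kinematics import JointAngleSeries

FeatureKind = Literal["angles", "correlation"]


@dataclass
class DTWResult:
    """Distance, optimal warping path and (optionally) the cost grid.

    ``path`` is a list of 0-based (u, v) index pairs from (0, 0) to
    (T1-1, T2-1); each step increments u, v or both by exactly one. The
    distance equals the sum of local costs along the path.
    """

    distance: float
    path: list[tuple[int, int]]
    cost_matrix: np.ndarray | None = None


@njit(cache=False)
def _accumulate(local: np.ndarray) -> np.ndarray:  # pragma: no cover - JIT
    n, m = local.shape
    D = np.empty((n, m))
    D[0, 0] = local[0, 0]
    for v in range(1, m):
        D[0, v] = D[0, v - 1] + local[0, v]
    for u in range(1, n):
        D[u, 0] = D[u - 1, 0] + local[u, 0]
        for v in range(1, m):
            best = D[u - 1, v - 1]
            if D[u - 1, v] < best:
                best = D[u - 1, v]
            if D[u, v - 1] < best:
                best = D[u, v - 1]
            D[u, v] = local[u, v] + best
    return D


def _backtrack(D: np.ndarray) -> list[tuple[int, int]]:
    """Recover the optimal path, preferring the diagonal step on ties."""
    u, v = D.shape[0] - 1, D.shape[1] - 1
    path = [(u, v)]
    while u > 0 or v > 0:
        if u == 0:
            v -= 1
        elif v == 0:
            u -= 1
        else:
            diag, up, left = D[u - 1, v - 1], D[u - 1, v], D[u, v - 1]
            if diag <= up and diag <= left:
                u -= 1
                v -= 1
            elif up <= left:
                u -= 1
            else:
                v -= 1
        path.append((u, v))
    path.reverse()
    return path


def local_cost(u_vec, v_vec) -> float:
    """Euclidean ground cost between two J-dimensional frames."""
    u_vec = np.atleast_1d(np.asarray(u_vec, dtype=float))
    v_vec = np.atleast_1d(np.asarray(v_vec, dtype=float))
    if u_vec.shape != v_vec.shape:
        raise ShapeMismatchError(f"dimensionality mismatch: {u_vec.shape} vs {v_vec.shape}")
    return float(np.linalg.norm(u_vec - v_vec))


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ShapeMismatchError("DTW input must be 1-D or (frames, dims)")
    return X


def dtw_distance(A, B, keep_cost_matrix: bool = False, keep_path: bool = True) -> DTWResult:
    """Dependent DTW between two (T, J) matrices (1-D inputs allowed)."""
    A = _as_matrix(A)
    B = _as_matrix(B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise InsufficientDataError("DTW needs at least one frame per sequence")
    if A.shape[1] != B.shape[1]:
        raise ShapeMismatchError(
            f"feature dimensionality mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    local = cdist(A, B, metric="euclidean")
    D = _accumulate(local)
    path = _backtrack(D) if keep_path else []
    return DTWResult(
        distance=float(D[-1, -1]),
        path=path,
        cost_matrix=D if keep_cost_matrix else None,
    )


def feature_distance(ref_feature, tgt_feature, feature_kind: FeatureKind = "angles") -> float:
    """DTW distance between two features of the same kind.

    ``angles``: DTW over the time axis of two angle series. ``correlation``:
    DTW over the J ordered rows of two correlation matrices, each row a
    J-dimensional vector.
    """
    if feature_kind == "angles":
        pair = []
        for f in (ref_feature, tgt_feature):
            if isinstance(f, CorrelationFeature):
                raise ConfigurationError("got a correlation feature under kind 'angles'")
            pair.append(f.values if isinstance(f, JointAngleSeries) else _as_matrix(f))
        return dtw_distance(pair[0], pair[1], keep_path=False).distance
    if feature_kind == "correlation":
        pair = []
        for f in (ref_feature, tgt_feature):
            if isinstance(f, JointAngleSeries):
                raise ConfigurationError("got an angle series under kind 'correlation'")
            mat = f.matrix if isinstance(f, CorrelationFeature) else _as_matrix(f)
            if mat.shape[0] != mat.shape[1]:
                raise ShapeMismatchError("correlation feature must be square")
            pair.append(mat)
        return dtw_distance(pair[0], pair[1], keep_path=False).distance
    raise ConfigurationError(f"unknown feature kind {feature_kind!r}")


def dump_alignment(result: DTWResult, path) -> None:
    """Write the accumulated-cost grid and warping path as JSON for
    cost-matrix heat-map visualization."""
    import json
    from pathlib import Path

    doc = {
        "distance": result.distance,
        "path": [list(p) for p in result.path],
        "cost_matrix": None if result.cost_matrix is None else result.cost_matrix.tolist(),
    }
    Path(path).write_text(json.dumps(doc))
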