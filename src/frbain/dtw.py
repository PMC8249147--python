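"""Multivariate dynamic time warping.

The distance between two records is the minimum, over all monotone
boundary-respecting warping paths with steps {(1,0),(0,1),(1,1)}, of the
cumulative Euclidean frame distance along the path:

    D(X, Y) = min_phi sum_n d(X(n), Y(phi(n)))

No slope constraint or windowing band is applied by default; an optional
Sakoe-Chiba band and an optional path-length normalisation are available.
The frame metric is the Euclidean norm across channels, which makes the
distance symmetric, nonnegative, and zero exactly on identical records.

``dtw_distance_brute`` enumerates every admissible path explicitly; it is an
independent reference for small inputs, kept deliberately separate from the
dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DimensionError, ValidationError
from .signal import Signal, SignalDataset

__all__ = [
    "DTWResult",
    "DistanceMatrix",
    "frame_distance",
    "dtw_distance",
    "dtw_distance_brute",
    "distance_matrix",
]

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap(a[0]) if a and callable(a[0]) else wrap


@dataclass
class DTWResult:
    """Distance plus the warping path that attains it (0-based index pairs)."""

    distance: float
    path: Optional[list] = None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise DTW distances over a set of records."""

    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("distances must be finite and nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_values(x: Union[Signal, np.ndarray]) -> np.ndarray:
    if isinstance(x, Signal):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def frame_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two same-length frame vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@njit(cache=False)
def _dp_full(cost):  # pragma: no cover - numba kernel
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i, j] + best
    return acc


def _cost_matrix(xa: np.ndarray, xb: np.ndarray, band: Optional[int]) -> np.ndarray:
    cost = cdist(xa.T, xb.T)
    if band is not None:
        n, m = cost.shape
        # widen so the corner-to-corner path always stays feasible
        w = max(int(band), abs(n - m))
        i = np.arange(n)[:, None]
        j = np.arange(m)[None, :]
        cost = np.where(np.abs(i - j) <= w, cost, np.inf)
    return cost


def _backtrack(acc: np.ndarray) -> list:
    """Recover one optimal path, preferring the diagonal step on ties."""
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d, u, l = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if d <= u and d <= l:
                i, j = i - 1, j - 1
            elif u <= l:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def dtw_distance(
    x: Union[Signal, np.ndarray],
    y: Union[Signal, np.ndarray],
    *,
    normalize: bool = False,
    band: Optional[int] = None,
    return_path: bool = True,
) -> DTWResult:
    """DTW distance between two records with the same channel count.

    Parameters
    ----------
    normalize : bool
        Divide the cumulative distance by the optimal path length.  Off by
        default; the raw minimum cumulative distance grows with record
        length.
    band : int, optional
        Sakoe-Chiba band half-width; cells with ``|i - j|`` beyond the band
        (widened to keep the endpoints reachable) are excluded.
    return_path : bool
        Also backtrack and return the optimal warping path.
    """
    xa, xb = _as_values(x), _as_values(y)
    if xa.shape[0] != xb.shape[0]:
        raise DimensionError(
            f"channel counts differ: {xa.shape[0]} vs {xb.shape[0]}"
        )
    cost = _cost_matrix(xa, xb, band)
    acc = _dp_full(cost)
    dist = float(acc[-1, -1])
    path = _backtrack(acc) if return_path else None
    if normalize:
        plen = len(path) if path is not None else len(_backtrack(acc))
        dist /= plen
    return DTWResult(distance=dist, path=path)


@lru_cache(maxsize=None)
def _paths_for_shape(n: int, m: int) -> tuple:
    """All admissible warping paths on an n x m grid (small n, m only)."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    out = []
    for pi, pj in {(n - 2, m - 2), (n - 2, m - 1), (n - 1, m - 2)}:
        if pi >= 0 and pj >= 0:
            for p in _paths_for_shape(pi + 1, pj + 1):
                out.append(p + ((n - 1, m - 1),))
    return tuple(out)


@lru_cache(maxsize=None)
def _path_indicator(n: int, m: int) -> np.ndarray:
    """(n_paths, n*m) 0/1 matrix: which grid cells each path visits."""
    paths = _paths_for_shape(n, m)
    mat = np.zeros((len(paths), n * m))
    for p, path in enumerate(paths):
        for i, j in path:
            mat[p, i * m + j] = 1.0
    return mat


def dtw_distance_brute(
    x: Union[Signal, np.ndarray], y: Union[Signal, np.ndarray]
) -> float:
    """Exhaustive-enumeration DTW distance (reference for small inputs)."""
    xa, xb = _as_values(x), _as_values(y)
    if xa.shape[0] != xb.shape[0]:
        raise DimensionError("channel counts differ")
    cost = cdist(xa.T, xb.T)
    sums = _path_indicator(cost.shape[0], cost.shape[1]) @ cost.ravel()
    return float(sums.min())


def distance_matrix(
    dataset: Union[SignalDataset, Sequence],
    subset: Optional[Sequence[int]] = None,
    *,
    normalize: bool = False,
    band: Optional[int] = None,
) -> DistanceMatrix:
    """Pairwise DTW distance matrix; computed for i < j and mirrored."""
    signals = list(dataset)
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValidationError("empty subset")
        signals = [signals[i] for i in subset]
    if not signals:
        raise ValidationError("empty dataset")
    n = len(signals)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(
                signals[i], signals[j],
                normalize=normalize, band=band, return_path=normalize,
            ).distance
            vals[i, j] = vals[j, i] = d
    ids = [
        s.record_id if isinstance(s, Signal) and s.record_id else str(k)
        for k, s in enumerate(signals)
    ]
    return DistanceMatrix(values=vals, ids=ids)
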