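"""Dynamic fuzzy clustering over DTW distance matrices.

Because averaging warped time series is ill-defined, the clustering runs in
relational (medoid) form directly on the pairwise DTW matrix: cluster
centers are always actual records.  A validity index trades in-cluster
compactness (coupling degree) against between-cluster separation, and the
cluster count is chosen at its minimum over a scanned range.  Per class, the
winning medoids become the "typical feature samples" stored as radial-basis
kernel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dtw import DistanceMatrix, distance_matrix
from .errors import DegenerateSeparationError, ValidationError
from .signal import Signal, SignalDataset

__all__ = [
    "FuzzyPartition",
    "ValidityScore",
    "KernelBank",
    "fuzzy_c_medoids",
    "coupling_degree",
    "separation_degree",
    "validity_index",
    "select_cluster_count",
    "build_kernel_bank",
]

logger = logging.getLogger(__name__)


@dataclass
class FuzzyPartition:
    """A fuzzy partition into ``c`` clusters with medoid centers.

    ``memberships`` is (c, n_samples) with columns on the simplex;
    ``objective`` is the fuzzy within-cluster cost
    ``sum_ij u_ij^fuzzifier * d(medoid_i, j)``.
    """

    memberships: np.ndarray
    medoid_indices: np.ndarray
    fuzzifier: float
    objective: float
    objective_history: list = field(default_factory=list)

    @property
    def c(self) -> int:
        return self.memberships.shape[0]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=0)


@dataclass
class ValidityScore:
    c: int
    coupling: float
    separation: float
    alpha: float
    gd: float


@dataclass
class KernelBank:
    """Typical-feature signals with (class, subclass) tags, class-major order.

    The bank is the model's embedded prior knowledge: every center is a
    verbatim member of the training set.
    """

    centers: list  # list of Signal
    class_index: np.ndarray  # class index per center
    subclass_index: np.ndarray  # subclass index within class, per center
    class_order: list  # class labels, index k <-> class_order[k]

    def __post_init__(self) -> None:
        self.class_index = np.asarray(self.class_index, dtype=int)
        self.subclass_index = np.asarray(self.subclass_index, dtype=int)
        if not (len(self.centers) == len(self.class_index) == len(self.subclass_index)):
            raise ValidationError("kernel bank fields have mismatched lengths")
        if len(self.class_index) > 1 and np.any(np.diff(self.class_index) < 0):
            raise ValidationError("kernel bank must be ordered class-major")

    @property
    def m(self) -> int:
        return len(self.centers)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def per_class_counts(self) -> np.ndarray:
        return np.bincount(self.class_index, minlength=self.n_classes)


def _as_dm(D: Union[DistanceMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    return arr


def _memberships_from_medoids(D: np.ndarray, medoids: np.ndarray,
                              fuzzifier: float) -> np.ndarray:
    """Standard FCM membership update from medoid-to-sample distances.

    u_ij = 1 / sum_h (d(i,j)/d(h,j))^(2/(fuzzifier-1)); a sample at zero
    distance from a medoid is assigned crisply to (the first) such medoid.
    """
    dm = D[medoids]  # (c, n)
    expo = 2.0 / (fuzzifier - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dm ** (-expo)
        u = inv / inv.sum(axis=0, keepdims=True)
    zero_cols = np.any(dm == 0.0, axis=0)
    if np.any(zero_cols):
        u[:, zero_cols] = 0.0
        first_zero = np.argmax(dm[:, zero_cols] == 0.0, axis=0)
        u[first_zero, np.nonzero(zero_cols)[0]] = 1.0
    return u


def _update_medoids(D: np.ndarray, u: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Per cluster, the sample minimising the fuzzy-weighted distance sum;
    medoids are kept distinct (greedy, next-best on collision)."""
    w = u ** fuzzifier  # (c, n)
    scores = D @ w.T  # (n_candidates, c)
    medoids = np.empty(u.shape[0], dtype=int)
    taken: set = set()
    for i in range(u.shape[0]):
        order = np.argsort(scores[:, i], kind="stable")
        for cand in order:
            if int(cand) not in taken:
                medoids[i] = int(cand)
                taken.add(int(cand))
                break
    return medoids


def _objective(D: np.ndarray, u: np.ndarray, medoids: np.ndarray,
               fuzzifier: float) -> float:
    return float(np.sum(u ** fuzzifier * D[medoids]))


def _spread_init(D: np.ndarray, c: int, start: int) -> np.ndarray:
    """Greedy farthest-point initialisation from a given start sample."""
    medoids = [start]
    for _ in range(c - 1):
        mind = D[medoids].min(axis=0)
        mind[medoids] = -1.0
        medoids.append(int(np.argmax(mind)))
    return np.array(medoids, dtype=int)


def _objective_for_medoids(D: np.ndarray, medoids, fuzzifier: float) -> float:
    u = _memberships_from_medoids(D, np.asarray(medoids, dtype=int), fuzzifier)
    return _objective(D, u, np.asarray(medoids, dtype=int), fuzzifier)


def _swap_refine(D: np.ndarray, medoids: np.ndarray,
                 fuzzifier: float, max_passes: int = 50) -> np.ndarray:
    """PAM-style local search: greedily swap a medoid for a non-medoid
    while the fuzzy objective (with memberships optimal for the candidate
    set) improves.  Escapes most local optima of the alternating updates."""
    n = D.shape[0]
    medoids = list(int(m) for m in medoids)
    current = _objective_for_medoids(D, medoids, fuzzifier)
    for _ in range(max_passes):
        best_gain, best_swap = 0.0, None
        in_set = set(medoids)
        for i, mi in enumerate(medoids):
            for q in range(n):
                if q in in_set:
                    continue
                cand = medoids.copy()
                cand[i] = q
                obj = _objective_for_medoids(D, cand, fuzzifier)
                if current - obj > best_gain + 1e-15:
                    best_gain, best_swap = current - obj, (i, q)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        current -= best_gain
    return np.array(medoids, dtype=int)


def fuzzy_c_medoids(
    D: Union[DistanceMatrix, np.ndarray],
    c: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    restarts: int = 1,
    exact_budget: int = 2000,
) -> FuzzyPartition:
    """Relational fuzzy c-medoids.

    Small problems (at most ``exact_budget`` candidate medoid sets) are
    solved exactly by enumerating every set and scoring it with its optimal
    memberships.  Larger ones use alternating optimisation with a PAM-style
    swap refinement: memberships and medoids are updated alternately until
    the objective decrease falls below ``tol``, and the converged medoid
    set is refined by greedy single-medoid swaps.  With ``restarts > 1``
    the best run (by final objective) is returned; the first restart uses a
    farthest-point initialisation, subsequent ones random seeded draws.
    """
    from math import comb

    Dv = _as_dm(D)
    n = Dv.shape[0]
    if not 1 <= c <= n:
        raise ValidationError(f"cluster count {c} not in [1, {n}]")
    if fuzzifier <= 1:
        raise ValidationError("fuzzifier must exceed 1")
    if c < n and comb(n, c) <= exact_budget:
        import itertools

        best_set, best_obj = None, np.inf
        for cand in itertools.combinations(range(n), c):
            obj = _objective_for_medoids(Dv, cand, fuzzifier)
            if obj < best_obj - 1e-15:
                best_set, best_obj = cand, obj
        medoids = np.array(best_set, dtype=int)
        u = _memberships_from_medoids(Dv, medoids, fuzzifier)
        return FuzzyPartition(memberships=u, medoid_indices=medoids,
                              fuzzifier=fuzzifier, objective=best_obj,
                              objective_history=[best_obj])
    rng = np.random.default_rng(seed)
    best: Optional[FuzzyPartition] = None
    for r in range(max(1, restarts)):
        if r == 0:
            medoids = _spread_init(Dv, c, start=int(np.argmin(Dv.sum(axis=0))))
        else:
            medoids = rng.choice(n, size=c, replace=False)
        if c < n:
            # refine the start by swaps before the alternating updates: the
            # monotone AO can then only improve on the swap-optimal start
            medoids = _swap_refine(Dv, medoids, fuzzifier)
        history: List[float] = []
        prev = np.inf
        u = _memberships_from_medoids(Dv, medoids, fuzzifier)
        for _ in range(max_iter):
            medoids = _update_medoids(Dv, u, fuzzifier)
            u = _memberships_from_medoids(Dv, medoids, fuzzifier)
            obj = _objective(Dv, u, medoids, fuzzifier)
            history.append(obj)
            if prev - obj < tol:
                break
            prev = obj
        if c < n:
            refined = _swap_refine(Dv, medoids, fuzzifier)
            if not np.array_equal(refined, medoids):
                medoids = refined
                u = _memberships_from_medoids(Dv, medoids, fuzzifier)
                history.append(_objective(Dv, u, medoids, fuzzifier))
        part = FuzzyPartition(
            memberships=u, medoid_indices=medoids,
            fuzzifier=fuzzifier, objective=history[-1],
            objective_history=history,
        )
        if best is None or part.objective < best.objective - 1e-15:
            best = part
    return best


def coupling_degree(p: FuzzyPartition, D: Union[DistanceMatrix, np.ndarray]) -> float:
    """In-cluster compactness: fuzzy-weighted mean distance to medoids,
    Cd = (1/N) sum_i sum_j u_ij^fuzzifier d(medoid_i, j)."""
    Dv = _as_dm(D)
    return _objective(Dv, p.memberships, p.medoid_indices, p.fuzzifier) / Dv.shape[0]


def separation_degree(p: FuzzyPartition, D: Union[DistanceMatrix, np.ndarray]) -> float:
    """Between-cluster separation: the minimum inter-medoid distance."""
    if p.c < 2:
        raise DegenerateSeparationError("separation undefined for a single cluster")
    Dv = _as_dm(D)
    sub = Dv[np.ix_(p.medoid_indices, p.medoid_indices)]
    iu = np.triu_indices(p.c, k=1)
    return float(sub[iu].min())


def validity_index(coupling: float, separation: float, alpha: float) -> float:
    """GD(c) = alpha*Cd(c) + (1-alpha)/Sd(c); smaller is better."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    if separation <= 0.0:
        raise DegenerateSeparationError("separation must be positive")
    return alpha * coupling + (1.0 - alpha) / separation


def select_cluster_count(
    D: Union[DistanceMatrix, np.ndarray],
    c_min: int = 2,
    c_max: int = 6,
    alpha: float = 0.8,
    fuzzifier: float = 2.0,
    restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Tuple[FuzzyPartition, List[ValidityScore]]:
    """Scan cluster counts and keep the partition with minimal GD(c).

    Cd carries distance units while 1/Sd carries inverse ones, so GD is
    only meaningful on a dimensionless scale: the matrix is rescaled by its
    mean off-diagonal distance before clustering and scoring (the fuzzy
    c-medoids updates depend on distance ratios only, so the partitions are
    unaffected; the reported Cd/Sd are on the rescaled scale).  Ties
    (within 1e-12) go to the smaller count.  Candidate counts whose
    separation degenerates to zero are scored GD = +inf and never win
    unless every candidate degenerates.
    """
    Dv = _as_dm(D)
    n = Dv.shape[0]
    if n > 1:
        mean_off = Dv[np.triu_indices(n, k=1)].mean()
        if mean_off > 0:
            Dv = Dv / mean_off
    if not 2 <= c_min <= c_max <= n - 1:
        raise ValidationError(
            f"need 2 <= c_min <= c_max <= N-1, got c_min={c_min}, "
            f"c_max={c_max}, N={n}"
        )
    scores: List[ValidityScore] = []
    best_part, best_gd = None, np.inf
    for c in range(c_min, c_max + 1):
        part = fuzzy_c_medoids(
            Dv, c, fuzzifier=fuzzifier, tol=tol, max_iter=max_iter,
            seed=seed + 1000 * c, restarts=restarts,
        )
        cd = coupling_degree(part, Dv)
        sd = separation_degree(part, Dv)
        try:
            gd = validity_index(cd, sd, alpha)
        except DegenerateSeparationError:
            gd = np.inf
        scores.append(ValidityScore(c=c, coupling=cd, separation=sd,
                                    alpha=alpha, gd=gd))
        if gd < best_gd - 1e-12:
            best_part, best_gd = part, gd
    if best_part is None:
        raise ValidationError("all candidate cluster counts were degenerate")
    return best_part, scores


def build_kernel_bank(
    dataset: SignalDataset,
    alpha: float = 0.8,
    fuzzifier: float = 2.0,
    c_ranges: Union[Tuple[int, int], Dict[object, Tuple[int, int]]] = (2, 6),
    seed: int = 0,
    restarts: int = 5,
    dtw_normalize: bool = False,
    band: Optional[int] = None,
) -> KernelBank:
    """Cluster each class separately and collect its medoids as kernel
    centers, class-major (Z_11..Z_1m1, Z_21..).

    ``c_ranges`` is either one (c_min, c_max) pair applied to every class or
    a mapping from class label to a pair.  A forced count is expressed as
    ``(c, c)``; the validity scan only runs when the range is nontrivial.
    Classes too small for the requested range are clamped (a lone sample
    becomes its own center, with a warning).
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    labels = np.array([s.label for s in dataset], dtype=object)
    if any(l is None for l in labels):
        raise ValidationError("all records must be labeled to build a bank")
    centers: List[Signal] = []
    class_idx: List[int] = []
    sub_idx: List[int] = []
    for k, cls in enumerate(dataset.classes):
        idx = np.nonzero(labels == cls)[0]
        if isinstance(c_ranges, dict):
            c_min, c_max = c_ranges[cls]
        else:
            c_min, c_max = c_ranges
        nk = len(idx)
        if nk == 1:
            logger.warning("class %r has a single record; using it as the "
                           "lone kernel center", cls)
            centers.append(dataset[int(idx[0])])
            class_idx.append(k)
            sub_idx.append(0)
            continue
        Dk = distance_matrix(dataset, subset=idx,
                             normalize=dtw_normalize, band=band)
        c_max_eff = min(c_max, nk - 1)
        c_min_eff = min(c_min, c_max_eff)
        if c_min_eff == c_max_eff or c_min_eff < 2:
            c_eff = max(1, c_min_eff)
            part = fuzzy_c_medoids(Dk, c_eff, fuzzifier=fuzzifier,
                                   seed=seed + 7919 * k, restarts=restarts)
        else:
            part, _ = select_cluster_count(
                Dk, c_min_eff, c_max_eff, alpha=alpha, fuzzifier=fuzzifier,
                restarts=restarts, seed=seed + 7919 * k,
            )
        for l, mi in enumerate(part.medoid_indices):
            centers.append(dataset[int(idx[mi])])
            class_idx.append(k)
            sub_idx.append(l)
    return KernelBank(centers=centers, class_index=np.array(class_idx),
                      subclass_index=np.array(sub_idx),
                      class_order=list(dataset.classes))
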