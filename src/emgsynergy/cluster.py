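"""Representative-synergy identification and between-group matching.

Synergy weight vectors from all subjects of a group are pooled (unit-norm),
clustered by Ward's method on Euclidean distances, and the cluster count h is
chosen with the gap statistic: within-cluster dispersion of the data is
compared against B reference datasets drawn uniformly inside the bounding box
of the pooled vectors, and the chosen h is the smallest satisfying

    Gap(h) >= Gap(h+1) - sd(h+1).

Clusters supported by at least one third of a group's subjects are called
subject-invariant; their centroids are paired across groups by maximizing
the total scalar product (cosine similarity of unit vectors), with pairs
below SP 0.75 reported as unmatched.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy import stats as _sps

from .exceptions import (
    EmptySetError,
    InsufficientSampleError,
    LabelError,
    OrderError,
)
from .nmf import SynergyDecomposition

DEFAULT_SP_THRESHOLD = 0.75
DEFAULT_H_RANGE = (2, 20)
DEFAULT_B = 500
DEFAULT_SUBJECT_FRACTION = 1.0 / 3.0


@dataclass
class PooledVectors:
    """Unit-norm synergy vectors pooled across a group, tagged by subject."""

    vectors: np.ndarray          # N x m
    subject_ids: list[str]       # length N
    muscle_labels: list[str] | None = None

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ClusterSolution:
    pooled: PooledVectors
    linkage: np.ndarray
    h: int
    gap_curve: np.ndarray        # columns: h, Gap(h), sd(h)
    gap_found: bool
    assignments: np.ndarray      # cluster id (1..h) per pooled vector
    centroids_raw: np.ndarray    # h x m, plain mean of member vectors
    centroids: np.ndarray        # h x m, means renormalized to unit norm
    support: np.ndarray          # distinct subjects per cluster


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]   # (cluster A, cluster B, SP)
    unmatched_A: list[int]
    unmatched_B: list[int]
    sp_threshold: float = DEFAULT_SP_THRESHOLD


def pool_group(
    decompositions: list[SynergyDecomposition],
    subject_ids: list[str] | None = None,
) -> PooledVectors:
    """Collect every subject's W columns into one unit-normalized set."""
    if not decompositions:
        raise EmptySetError("no decompositions to pool")
    if subject_ids is None:
        subject_ids = [f"S{i + 1}" for i in range(len(decompositions))]
    labels = decompositions[0].muscle_labels
    vecs, tags = [], []
    for sid, dec in zip(subject_ids, decompositions):
        if dec.muscle_labels != labels:
            raise LabelError(f"subject {sid} has different muscle labels")
        W = np.asarray(dec.W, dtype=float)
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        for j in range(W.shape[1]):
            vecs.append(W[:, j] / norms[j])
            tags.append(sid)
    return PooledVectors(vectors=np.array(vecs), subject_ids=tags,
                         muscle_labels=labels)


def ward_cluster(vectors: np.ndarray, h: int) -> np.ndarray:
    """Ward/Euclidean agglomeration cut at ``h`` clusters (ids 1..h)."""
    vectors = np.asarray(vectors, dtype=float)
    if h < 1:
        raise OrderError("cluster count must be >= 1")
    if h > vectors.shape[0]:
        raise OrderError(f"h={h} exceeds {vectors.shape[0]} vectors")
    Z = linkage(vectors, method="ward")
    return fcluster(Z, t=h, criterion="maxclust")


def _dispersion(vectors: np.ndarray, assignments: np.ndarray) -> float:
    """Tibshirani's pooled within-cluster dispersion sum_r D_r / (2 n_r).

    Uses the identity D_r / (2 n_r) = sum of squared distances to the
    cluster mean.
    """
    total = 0.0
    for cid in np.unique(assignments):
        member = vectors[assignments == cid]
        total += float(((member - member.mean(axis=0)) ** 2).sum())
    return total


def gap_statistic(
    vectors: np.ndarray,
    h_range: tuple[int, int] = DEFAULT_H_RANGE,
    B: int = DEFAULT_B,
    seed: int = 0,
    sd_correction: bool = True,
    renormalize_refs: bool = False,
) -> tuple[np.ndarray, int, bool]:
    """Gap-statistic choice of the cluster count.

    Reference sets are drawn uniformly within the per-dimension min/max of
    the data (optionally renormalized to unit vectors) and clustered by the
    same Ward procedure. Returns ``(curve, h_star, found)`` where ``curve``
    has rows (h, Gap(h), sd(h)); sd includes the sqrt(1 + 1/B) simulation
    correction unless disabled.
    """
    vectors = np.asarray(vectors, dtype=float)
    h_lo, h_hi = h_range
    if h_lo < 1 or h_hi < h_lo:
        raise OrderError(f"invalid h range {h_range}")
    if vectors.shape[0] < h_hi + 1:
        raise OrderError(
            f"{vectors.shape[0]} vectors cannot support h up to {h_hi}")
    if B < 2:
        raise ValueError("need at least B=2 reference datasets")
    if B < 10:
        warnings.warn(f"B={B} reference datasets is very small", stacklevel=2)

    rng = np.random.default_rng(seed)
    lo = vectors.min(axis=0)
    hi = vectors.max(axis=0)
    n, m = vectors.shape

    hs = np.arange(h_lo, h_hi + 1)
    log_w = np.empty(hs.size)
    log_wb = np.empty((B, hs.size))

    Z = linkage(vectors, method="ward")
    for i, h in enumerate(hs):
        log_w[i] = np.log(_dispersion(vectors, fcluster(Z, t=h, criterion="maxclust")))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=(n, m))
        if renormalize_refs:
            norms = np.linalg.norm(ref, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            ref = ref / norms
        Zb = linkage(ref, method="ward")
        for i, h in enumerate(hs):
            log_wb[b, i] = np.log(
                _dispersion(ref, fcluster(Zb, t=h, criterion="maxclust")))

    gap = log_wb.mean(axis=0) - log_w
    sd = log_wb.std(axis=0)
    if sd_correction:
        sd = sd * np.sqrt(1.0 + 1.0 / B)

    h_star, found = int(hs[-1]), False
    for i in range(hs.size - 1):
        if gap[i] >= gap[i + 1] - sd[i + 1]:
            h_star, found = int(hs[i]), True
            break
    curve = np.column_stack([hs, gap, sd])
    return curve, h_star, found


def cluster_group(
    pooled: PooledVectors,
    h_range: tuple[int, int] = DEFAULT_H_RANGE,
    B: int = DEFAULT_B,
    seed: int = 0,
    h: int | None = None,
) -> ClusterSolution:
    """Cluster a group's pooled vectors; pick h by gap statistic unless given."""
    vectors = pooled.vectors
    if h is None:
        h_hi = min(h_range[1], len(pooled) - 1)
        curve, h, found = gap_statistic(vectors, (h_range[0], h_hi), B, seed)
    else:
        curve, found = np.empty((0, 3)), True
    Z = linkage(vectors, method="ward")
    assignments = fcluster(Z, t=h, criterion="maxclust")
    cids = np.arange(1, h + 1)
    raw = np.array([vectors[assignments == c].mean(axis=0) for c in cids])
    unit = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    support = np.array([
        len({pooled.subject_ids[i] for i in np.flatnonzero(assignments == c)})
        for c in cids
    ])
    return ClusterSolution(pooled=pooled, linkage=Z, h=int(h), gap_curve=curve,
                           gap_found=found, assignments=assignments,
                           centroids_raw=raw, centroids=unit, support=support)


def subject_invariant(
    solution: ClusterSolution,
    group_size: int,
    fraction: float = DEFAULT_SUBJECT_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep clusters whose members come from >= ceil(fraction * group_size)
    distinct subjects. Returns (cluster ids kept, their unit centroids)."""
    need = ceil(fraction * group_size)
    keep = np.flatnonzero(solution.support >= need)
    return keep + 1, solution.centroids[keep]


def match_groups(
    centroids_A: np.ndarray,
    centroids_B: np.ndarray,
    sp_threshold: float = DEFAULT_SP_THRESHOLD,
    ids_A: np.ndarray | None = None,
    ids_B: np.ndarray | None = None,
) -> MatchResult:
    """Pair centroids across groups maximizing the total scalar product.

    Solved as an optimal assignment (exact for every instance size); pairs
    whose SP falls below the threshold are demoted to unmatched.
    """
    A = np.atleast_2d(np.asarray(centroids_A, dtype=float))
    Bm = np.atleast_2d(np.asarray(centroids_B, dtype=float))
    if A.size == 0 or Bm.size == 0:
        na = 0 if A.size == 0 else A.shape[0]
        nb = 0 if Bm.size == 0 else Bm.shape[0]
        return MatchResult(pairs=[], unmatched_A=list(range(na)),
                           unmatched_B=list(range(nb)),
                           sp_threshold=sp_threshold)
    ids_A = np.arange(A.shape[0]) if ids_A is None else np.asarray(ids_A)
    ids_B = np.arange(Bm.shape[0]) if ids_B is None else np.asarray(ids_B)
    sp = A @ Bm.T
    row, col = linear_sum_assignment(-sp)
    pairs, matched_a, matched_b = [], set(), set()
    for i, j in sorted(zip(row, col)):
        if sp[i, j] >= sp_threshold:
            pairs.append((int(ids_A[i]), int(ids_B[j]), float(sp[i, j])))
            matched_a.add(i)
            matched_b.add(j)
    unmatched_A = [int(ids_A[i]) for i in range(A.shape[0]) if i not in matched_a]
    unmatched_B = [int(ids_B[j]) for j in range(Bm.shape[0]) if j not in matched_b]
    return MatchResult(pairs=pairs, unmatched_A=unmatched_A,
                       unmatched_B=unmatched_B, sp_threshold=sp_threshold)


def brute_force_match(centroids_A: np.ndarray, centroids_B: np.ndarray) -> float:
    """Exhaustive-enumeration optimum of the total SP over pairings.

    Exponential; intended as an independent cross-check on small instances.
    """
    A = np.atleast_2d(centroids_A)
    Bm = np.atleast_2d(centroids_B)
    sp = A @ Bm.T
    na, nb = sp.shape
    k = min(na, nb)
    best = -np.inf
    for rows in itertools.combinations(range(na), k):
        for cols in itertools.permutations(range(nb), k):
            best = max(best, sum(sp[r, c] for r, c in zip(rows, cols)))
    return float(best)


@dataclass
class TemporalComparison:
    t_profile: np.ndarray
    threshold: float
    clusters: list[tuple[int, int]] = field(default_factory=list)


def compare_temporal(
    patterns_A: np.ndarray,
    patterns_B: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TemporalComparison:
    """Pointwise two-sample t-trajectory with max-statistic permutation
    correction over time.

    ``patterns_A``/``patterns_B`` are (subjects x timepoints) averaged
    temporal patterns of one matched synergy pair. Group labels are permuted
    to build the null distribution of the maximum |t| across time; the
    (1 - alpha) quantile is the significance threshold, and contiguous
    supra-threshold runs are returned as (start, stop) inclusive index pairs.
    """
    A = np.atleast_2d(np.asarray(patterns_A, dtype=float))
    Bm = np.atleast_2d(np.asarray(patterns_B, dtype=float))
    if A.shape[0] < 2 or Bm.shape[0] < 2:
        raise InsufficientSampleError("need >= 2 subjects per group")
    if A.shape[1] != Bm.shape[1]:
        raise ValueError("temporal patterns must share length")

    def t_profile(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return _sps.ttest_ind(a, b, axis=0, equal_var=True).statistic

    obs = t_profile(A, Bm)
    pooled = np.vstack([A, Bm])
    n_a = A.shape[0]
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    idx = np.arange(pooled.shape[0])
    for p in range(n_perm):
        rng.shuffle(idx)
        null_max[p] = np.nanmax(np.abs(t_profile(pooled[idx[:n_a]],
                                                 pooled[idx[n_a:]])))
    thresh = float(np.quantile(null_max, 1.0 - alpha))

    sig = np.abs(obs) > thresh
    clusters: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(sig) - 1))
    return TemporalComparison(t_profile=obs, threshold=thresh, clusters=clusters)
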