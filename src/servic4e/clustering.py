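"""k-medoid (PAM) clustering with silhouette-based model selection.

Two filtering stages of the cascade are built on this module:

* the cross-pool positive/negative split at each candidate site, clustering
  pools in (continuity, WAF) space so that pools lacking the variant allele
  act as a baseline; and
* the global average-quality cutoff, clustering all candidates in
  (average quality, log10 WAF) space and keeping only the high-quality mode.

PAM is implemented here (BUILD initialisation followed by greedy SWAP) and is
fully deterministic: ties are broken by lowest index, so a seed only exists
for API symmetry.  The average silhouette width used for choosing k comes
from scikit-learn, with the all-singleton convention (silhouette 0) handled
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import pairwise_distances, silhouette_score


@dataclass
class ClusterResult:
    k: int
    medoids: np.ndarray  # indices into the point array
    labels: np.ndarray  # point -> cluster (index into medoids)
    avg_silhouette: float  # NaN when k == 1
    cost: float  # total distance of points to their medoid

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    dm = D[:, medoids]
    labels = dm.argmin(axis=1)
    return labels, float(dm.min(axis=1).sum())


def k_medoids(points: np.ndarray, k: int, seed: int = 1) -> ClusterResult:
    """k-medoid clustering under the PAM objective; deterministic.

    ``points`` is an (n, d) array; Euclidean distances.  Small search spaces
    (C(n, k) <= 1000) are solved exactly by enumerating medoid sets; larger
    ones use PAM BUILD followed by best-improvement SWAP passes.  Ties in
    every argmin are broken by lowest index.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    D = pairwise_distances(X)

    if math.comb(n, k) <= 1000:
        return _k_medoids_exact(X, D, k)

    # BUILD: start with the point minimising total distance, then greedily
    # add the point giving the largest cost reduction.
    medoids = [int(D.sum(axis=0).argmin())]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(0.0, d_near[:, None] - D).sum(axis=0)
        gain[medoids] = -1.0
        j = int(gain.argmax())
        medoids.append(j)
        d_near = np.minimum(d_near, D[:, j])

    # SWAP: best-improvement passes.
    medoids_arr = np.array(sorted(medoids))
    while True:
        dm = D[:, medoids_arr]
        order = dm.argsort(axis=1, kind="stable")
        d1 = np.take_along_axis(dm, order[:, :1], axis=1)[:, 0]
        nearest = medoids_arr[order[:, 0]]
        if k > 1:
            d2 = np.take_along_axis(dm, order[:, 1:2], axis=1)[:, 0]
        else:
            d2 = np.full(len(X), np.inf)

        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        for mi, m in enumerate(medoids_arr):
            mine = nearest == m
            # removing m: its points move to their second-best or to h
            gain_mine = np.minimum(D[mine], d2[mine, None]).sum(axis=0) - d1[mine].sum()
            gain_other = np.minimum(0.0, D[~mine] - d1[~mine, None]).sum(axis=0)
            delta = gain_mine + gain_other  # vector over candidate h
            delta[medoids_arr] = np.inf
            h = int(delta.argmin())
            if delta[h] < best_delta:
                best_delta = float(delta[h])
                best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids_arr[mi] = h
        medoids_arr = np.sort(medoids_arr)

    labels, cost = _assign(D, medoids_arr)
    sil = average_silhouette(X, labels) if 1 < k < n else (0.0 if k == n else math.nan)
    return ClusterResult(k=k, medoids=medoids_arr, labels=labels,
                         avg_silhouette=sil, cost=cost)


def _k_medoids_exact(X: np.ndarray, D: np.ndarray, k: int) -> ClusterResult:
    import itertools

    n = len(X)
    best_cost = np.inf
    best: tuple[int, ...] | None = None
    for combo in itertools.combinations(range(n), k):
        cost = D[:, combo].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = combo
    assert best is not None
    medoids_arr = np.array(best)
    labels, cost = _assign(D, medoids_arr)
    sil = average_silhouette(X, labels) if 1 < k < n else (0.0 if k == n else math.nan)
    return ClusterResult(k=k, medoids=medoids_arr, labels=labels,
                         avg_silhouette=sil, cost=cost)


def average_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width; 0.0 by convention when every cluster is a
    singleton, NaN for a single cluster."""
    labels = np.asarray(labels)
    n_labels = len(np.unique(labels))
    n = len(labels)
    if n_labels <= 1:
        return math.nan
    if n_labels >= n:
        return 0.0
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return float(silhouette_score(X, labels))


def select_k_by_silhouette(
    points: np.ndarray,
    k_max: int | None = None,
    s_min: float = 0.25,
    seed: int = 1,
) -> ClusterResult:
    """Choose k in 2..k_max by maximal average silhouette width.

    When the best silhouette falls below ``s_min`` (no convincing structure)
    a single cluster is declared.  Fewer than two points are trivially a
    single cluster.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < 2:
        return ClusterResult(
            k=1, medoids=np.zeros(min(n, 1), dtype=int),
            labels=np.zeros(n, dtype=int), avg_silhouette=math.nan, cost=0.0,
        )
    if k_max is None:
        k_max = n - 1
    ks = list(range(2, min(k_max, n - 1) + 1)) or [2]
    best: ClusterResult | None = None
    for k in ks:
        res = k_medoids(X, k, seed=seed)
        if best is None or res.avg_silhouette > best.avg_silhouette + 1e-12:
            best = res
    assert best is not None
    if not (best.avg_silhouette >= s_min):
        one = k_medoids(X, 1, seed=seed)
        return one
    return best


def standardize(points: np.ndarray) -> np.ndarray:
    """Z-score each feature; constant features are zeroed."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def positive_pools(
    stats_by_pool: Mapping[int, tuple[float, float]],
    waf_floor: float,
    s_min: float = 0.25,
    k_max: int = 6,
    seed: int = 1,
) -> set[int]:
    """Split pools at one site into positives and baseline negatives.

    ``stats_by_pool`` maps every pool (including zero-signal pools) to its
    (continuity, WAF) for the site's alternate allele.  Pools are clustered
    in standardized (C, w) space.  Retained are the cluster whose medoid has
    the highest (WAF, continuity) plus any other cluster whose medoid WAF
    reaches ``waf_floor``: for a rare variant only the high cluster stands
    out, while for a common variant every cluster except the near-zero
    baseline (negative pools) survives.  When no cluster structure is found,
    pools above ``waf_floor`` are kept.
    """
    pool_ids = sorted(stats_by_pool)
    C = np.array([stats_by_pool[p][0] for p in pool_ids], dtype=float)
    w = np.array([stats_by_pool[p][1] for p in pool_ids], dtype=float)
    if len(pool_ids) == 0:
        return set()
    X = standardize(np.column_stack([C, w]))
    res = select_k_by_silhouette(X, k_max=min(k_max, len(pool_ids) - 1),
                                 s_min=s_min, seed=seed)
    if res.k == 1:
        return {p for p, wi in zip(pool_ids, w) if wi >= waf_floor}
    med_rank = [(w[m], C[m]) for m in res.medoids]
    best = max(med_rank)
    keep: set[int] = set()
    for ci, (med_w, _) in enumerate(med_rank):
        if med_rank[ci] == best or med_w >= waf_floor:
            keep.update(pool_ids[i] for i in res.members(ci))
    return keep


def quality_cutoff(
    qualities: Sequence[float],
    wafs: Sequence[float],
    manual_cutoff: float | None = None,
    s_min: float = 0.25,
    k_max: int = 6,
    seed: int = 1,
) -> np.ndarray:
    """Indices of candidates retained by the global average-quality filter.

    Candidates are clustered in standardized (avg quality, log10 WAF) space
    and the cluster(s) whose medoid has the highest average quality are kept.
    A ``manual_cutoff`` (keep q >= cutoff) overrides clustering entirely.
    """
    q = np.asarray(qualities, dtype=float)
    w = np.asarray(wafs, dtype=float)
    if len(q) == 0:
        return np.array([], dtype=int)
    if manual_cutoff is not None:
        return np.flatnonzero(q >= manual_cutoff)
    X = standardize(np.column_stack([q, np.log10(np.maximum(w, 1e-12))]))
    res = select_k_by_silhouette(X, k_max=min(k_max, len(q) - 1),
                                 s_min=s_min, seed=seed)
    if res.k == 1:
        return np.arange(len(q))
    med_q = np.array([q[m] for m in res.medoids])
    best = med_q.max()
    keep = np.zeros(len(q), dtype=bool)
    for ci in np.flatnonzero(med_q == best):
        keep[res.members(int(ci))] = True
    return np.flatnonzero(keep)
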