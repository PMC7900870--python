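"""Affinity-maximizing clustering: coordinate ascent with random restarts.

The estimator :class:`CircaClustering` fits a hard partition of n items to a
(possibly sparse) soft similarity matrix by maximizing the affinity alpha
(see :mod:`circa.agreement`).  Each restart runs single-item coordinate
ascent from a uniform-random initial clustering; the best restart wins.
:func:`brute_force_best` is an exact enumeration oracle for tiny instances.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._ascent import _ascend
from .agreement import affinity
from .datatypes import FitResult, Partition, SimilarityMatrix

__all__ = [
    "CircaClustering",
    "coordinate_ascent",
    "circa_fit",
    "brute_force_best",
]


def _as_similarity(S: Union[SimilarityMatrix, np.ndarray]) -> SimilarityMatrix:
    if isinstance(S, SimilarityMatrix):
        return S
    return SimilarityMatrix.dense(np.asarray(S, dtype=np.float64))


def _subseeds(seed: Optional[int], n: int) -> np.ndarray:
    """Derive n independent 31-bit subseeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def _prepare_arrays(S: SimilarityMatrix):
    sim = np.where(S.observed, S.values, 0.0).astype(np.float64)
    obs = S.observed.astype(np.float64)
    return np.ascontiguousarray(sim), np.ascontiguousarray(obs)


def coordinate_ascent(S: Union[SimilarityMatrix, np.ndarray], k: int,
                      seed: Optional[int] = None) -> FitResult:
    """One coordinate-ascent run from a random initial clustering.

    Proposes moving a random item to a random other cluster; accepts iff the
    affinity strictly increases.  After n(k-1) consecutive rejections an
    exhaustive sweep over all single-item moves either certifies the local
    maximum (termination) or applies the best improving move and resumes.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = _as_similarity(S)
    if S.n_observed_pairs() == 0:
        raise ValueError("similarity matrix has no observed pairs")
    sim, obs = _prepare_arrays(S)
    subseed = int(_subseeds(seed, 1)[0])
    labels, num, pairs, proposals, accepted = _ascend(sim, obs, k, subseed)
    return FitResult(
        best=Partition(np.asarray(labels, dtype=np.int64), k),
        alpha=float(num / pairs),
        restarts=1,
        accepted_moves=int(accepted),
        proposals=int(proposals),
        seed=seed,
    )


def circa_fit(S: Union[SimilarityMatrix, np.ndarray], k: int,
              n_restarts: int = 100, seed: Optional[int] = None) -> FitResult:
    """Best-affinity result over ``n_restarts`` independent ascent runs.

    Restart r uses a subseed derived from ``seed``, so results are
    reproducible and the restart stream is a prefix: increasing
    ``n_restarts`` under the same seed never decreases the best alpha.
    Ties keep the first occurrence.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    S = _as_similarity(S)
    if S.n_observed_pairs() == 0:
        raise ValueError("similarity matrix has no observed pairs")
    sim, obs = _prepare_arrays(S)
    subseeds = _subseeds(seed, n_restarts)
    best_labels = None
    best_num = -np.inf
    pairs = 0.0
    tot_prop = 0
    tot_acc = 0
    for r in range(n_restarts):
        labels, num, pairs, proposals, accepted = _ascend(sim, obs, k, int(subseeds[r]))
        tot_prop += int(proposals)
        tot_acc += int(accepted)
        if num > best_num:
            best_num = num
            best_labels = np.asarray(labels, dtype=np.int64).copy()
    return FitResult(
        best=Partition(best_labels, k),
        alpha=float(best_num / pairs),
        restarts=n_restarts,
        accepted_moves=tot_acc,
        proposals=tot_prop,
        seed=seed,
    )


def _set_partitions_upto_k(n: int, k: int):
    """Yield every partition of n items into at most k blocks.

    Enumerated as restricted-growth strings, so each set partition appears
    exactly once (no relabeled duplicates).
    """
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for b in range(min(n_used + 1, k)):
            labels[i] = b
            yield from rec(i + 1, max(n_used, b + 1))

    yield from rec(1, 1)


def brute_force_best(S: Union[SimilarityMatrix, np.ndarray], k: int) -> FitResult:
    """Exact global affinity maximizer by enumeration (test oracle).

    Guards against instances with more than 10^7 candidate assignments.
    """
    S = _as_similarity(S)
    n = S.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k ** n > 10 ** 7:
        raise ValueError("instance too large to enumerate")
    iu, ju, s = S.observed_pairs()
    if s.size == 0:
        raise ValueError("similarity matrix has no observed pairs")
    best_labels = None
    best_num = -np.inf
    count = 0
    for labels in _set_partitions_upto_k(n, k):
        count += 1
        same = labels[iu] == labels[ju]
        num = float(np.where(same, s, 1.0 - s).sum())
        if num > best_num:
            best_num = num
            best_labels = labels
    return FitResult(
        best=Partition(best_labels, k),
        alpha=best_num / s.size,
        restarts=count,
        accepted_moves=0,
        proposals=count,
        seed=None,
    )


class CircaClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering of a precomputed soft similarity matrix.

    Maximizes the affinity between a hard partition and the soft pairwise
    similarity matrix by coordinate ascent with random restarts.

    Parameters
    ----------
    n_clusters : int, default=2
        Upper bound on the number of clusters (clusters may end up empty;
        see ``n_effective_clusters_``).
    n_restarts : int, default=100
        Independent random initializations; the best-affinity run wins.
    random_state : int or None
        Seed for the restart stream.

    Attributes
    ----------
    labels_ : ndarray of shape (n_items,)
        Cluster id per item.
    alpha_ : float
        Affinity of the fitted partition (1 = perfect agreement).
    n_effective_clusters_ : int
        Number of non-empty clusters in the fitted partition.
    fit_result_ : FitResult
        Full record (partition, counters, seed).

    Examples
    --------
    >>> import numpy as np
    >>> from circa.cluster import CircaClustering
    >>> from circa.similarity import comembership
    >>> from circa.datatypes import Partition
    >>> S = comembership(Partition(np.array([0, 0, 1, 1]), 2))
    >>> CircaClustering(n_clusters=2, n_restarts=5, random_state=0).fit(S).alpha_
    1.0
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 100,
                 random_state: Optional[int] = None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X: Union[SimilarityMatrix, np.ndarray], y=None) -> "CircaClustering":
        """Fit to a precomputed similarity matrix (SimilarityMatrix or square array)."""
        S = _as_similarity(X)
        result = circa_fit(S, self.n_clusters, n_restarts=self.n_restarts,
                           seed=self.random_state)
        self.fit_result_ = result
        self.labels_ = result.best.assignments
        self.alpha_ = result.alpha
        self.n_effective_clusters_ = result.best.n_effective_clusters()
        self.n_features_in_ = S.n
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def score(self, X, y=None) -> float:
        """Affinity of the fitted partition against a (validation) matrix X."""
        S = _as_similarity(X)
        return float(affinity(self.fit_result_.best, S))
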