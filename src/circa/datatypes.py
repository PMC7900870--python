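"""Core in-memory containers shared by all modules.

Items are dense 0-based integers internally; external string ids are mapped
through :attr:`SimilarityMatrix.item_ids` (and the readers in :mod:`circa.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Partition",
    "SimilarityMatrix",
    "TrialRecord",
    "ParticipantSort",
    "AgreementScore",
    "FitResult",
    "n_pairs",
]


def n_pairs(n: int) -> int:
    """Number of unordered item pairs, n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


@dataclass
class Partition:
    """A hard assignment of ``n`` items to at most ``k`` clusters.

    Parameters
    ----------
    assignments:
        Length-``n`` integer array; ``assignments[i]`` is the cluster id of
        item ``i``, in ``0..k-1``.
    k:
        Upper bound on the number of clusters.  Clusters may be empty; the
        number of *non-empty* clusters is :meth:`n_effective_clusters`.
    """

    assignments: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.ndim != 1 or self.assignments.size < 1:
            raise ValueError("assignments must be a non-empty 1-D array")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise ValueError("cluster ids must lie in 0..k-1")

    @property
    def n(self) -> int:
        return int(self.assignments.size)

    def n_effective_clusters(self) -> int:
        return int(np.unique(self.assignments).size)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)

    def relabeled(self, perm: Sequence[int]) -> "Partition":
        """Apply a cluster-id permutation (sanity tool for invariance tests)."""
        perm = np.asarray(perm, dtype=np.int64)
        return Partition(perm[self.assignments], self.k)

    @classmethod
    def from_labels(cls, labels: Sequence[int], k: Optional[int] = None) -> "Partition":
        labels = np.asarray(labels, dtype=np.int64)
        if k is None:
            k = int(labels.max()) + 1 if labels.size else 1
        return cls(labels, k)


@dataclass
class SimilarityMatrix:
    """Symmetric soft co-membership matrix with an observation mask.

    ``values[i, j]`` is the proportion of judgements calling items ``i`` and
    ``j`` the same category (in ``[0, 1]``), defined only where
    ``observed[i, j]`` is True.  ``counts[i, j]`` is the number of judgements
    contributing to that proportion.  The diagonal is unused.
    """

    values: np.ndarray
    observed: np.ndarray
    counts: np.ndarray
    item_ids: Optional[list] = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        o = np.asarray(self.observed, dtype=bool)
        c = np.asarray(self.counts, dtype=np.int64)
        if v.shape != o.shape or v.shape != c.shape or v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values, observed and counts must be equal square matrices")
        np.fill_diagonal(o, False)
        if not (np.array_equal(o, o.T)):
            raise ValueError("observed mask must be symmetric")
        if not np.allclose(np.where(o, v, 0.0), np.where(o, v, 0.0).T):
            raise ValueError("values must be symmetric where observed")
        if not np.array_equal(np.where(o, c, 0), np.where(o, c, 0).T):
            raise ValueError("counts must be symmetric where observed")
        vo = v[o]
        if vo.size and (vo.min() < -1e-12 or vo.max() > 1 + 1e-12):
            raise ValueError("observed values must lie in [0, 1]")
        if c[o].size and c[o].min() < 1:
            raise ValueError("counts must be >= 1 wherever observed")
        self.values, self.observed, self.counts = v, o, c

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def fully_observed(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(self.observed[off].all())

    def n_observed_pairs(self) -> int:
        return int(np.triu(self.observed, 1).sum())

    def observed_fraction(self) -> float:
        return self.n_observed_pairs() / n_pairs(self.n)

    def observed_pairs(self):
        """Upper-triangle indices and values of observed pairs: (i, j, s)."""
        iu, ju = np.where(np.triu(self.observed, 1))
        return iu, ju, self.values[iu, ju]

    @classmethod
    def dense(cls, values: np.ndarray, counts: Optional[np.ndarray] = None,
              item_ids: Optional[list] = None) -> "SimilarityMatrix":
        """Fully observed matrix (every off-diagonal pair judged)."""
        values = np.asarray(values, dtype=np.float64)
        n = values.shape[0]
        observed = ~np.eye(n, dtype=bool)
        if counts is None:
            counts = np.ones((n, n), dtype=np.int64)
        return cls(values, observed, counts, item_ids=item_ids)


@dataclass(frozen=True)
class TrialRecord:
    """One same/different judgement on an item pair."""

    item_i: int
    item_j: int
    same: bool
    participant: Optional[str] = None
    left_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.item_i == self.item_j:
            raise ValueError("a trial must compare two distinct items")


@dataclass
class ParticipantSort:
    """One participant's free-sort: a partition plus 1-5 free-text labels per category."""

    partition: Partition
    labels: dict[int, list[str]]

    def __post_init__(self) -> None:
        occupied = set(np.unique(self.partition.assignments).tolist())
        for c in occupied:
            labs = self.labels.get(c, [])
            if not labs:
                raise ValueError(f"cluster {c} has members but no label")
            if any((not isinstance(s, str)) or not s.strip() for s in labs):
                raise ValueError(f"cluster {c} has an empty label string")


@dataclass(frozen=True)
class AgreementScore:
    """A Rand-family agreement value with provenance.

    ``kind`` is one of ``{"RI", "ARI", "affinity", "softARI"}``.  ``n_random``
    and ``seed`` record the Monte-Carlo chance baseline for the soft ARI
    (0/None for deterministic scores).
    """

    value: float
    kind: str
    n_random: int = 0
    seed: Optional[int] = None

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class FitResult:
    """Outcome of an affinity-maximization run."""

    best: Partition
    alpha: float
    restarts: int
    accepted_moves: int
    proposals: int
    seed: Optional[int] = None

    def n_effective_clusters(self) -> int:
        return self.best.n_effective_clusters()
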