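"""Rand-family agreement indices.

Four scores:

* ``rand_index`` — fraction of item pairs two hard partitions agree on.
* ``adjusted_rand_index`` — the Hubert-Arabie chance-corrected Rand index.
* ``affinity`` — the generalization of the Rand index to a *soft* similarity
  matrix S: the mean, over judged pairs, of ``s_ij`` when the clustering puts
  the pair together and ``1 - s_ij`` when it splits them,

      alpha = (1 / P) * sum_{j>i observed} [ (c_i = c_j) s_ij + (c_i != c_j)(1 - s_ij) ]

  with P the number of observed pairs (P = n(n-1)/2 when S is fully
  observed).  alpha = 1 means the clustering perfectly reproduces every
  judged pair.
* ``soft_ari`` — a chance-corrected affinity, ``(RI_m - RI_r) / (1 - RI_r)``,
  where the chance term RI_r is estimated by Monte-Carlo over uniformly
  random partitions with the same number of non-empty clusters.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import AgreementScore, Partition, SimilarityMatrix, n_pairs
from .similarity import comembership

__all__ = [
    "rand_index",
    "adjusted_rand_index",
    "affinity",
    "soft_ari",
    "random_partition",
]


def _check_same_items(p: Partition, q: Partition) -> None:
    if p.n != q.n:
        raise ValueError("partitions must cover the same item set")
    if p.n < 2:
        raise ValueError("agreement indices need at least two items")


def _contingency(p: Partition, q: Partition) -> np.ndarray:
    kp = int(p.assignments.max()) + 1
    kq = int(q.assignments.max()) + 1
    table = np.zeros((kp, kq), dtype=np.int64)
    np.add.at(table, (p.assignments, q.assignments), 1)
    return table


def rand_index(p: Partition, q: Partition) -> AgreementScore:
    """Fraction of pairs on which two hard partitions agree (1 = identical)."""
    _check_same_items(p, q)
    table = _contingency(p, q)
    n = p.n
    # agreeing pairs = together-in-both + apart-in-both, via pair-count algebra
    sum_nij2 = int((table * (table - 1) // 2).sum())
    sum_a2 = int((table.sum(1) * (table.sum(1) - 1) // 2).sum())
    sum_b2 = int((table.sum(0) * (table.sum(0) - 1) // 2).sum())
    total = n_pairs(n)
    disagree = (sum_a2 - sum_nij2) + (sum_b2 - sum_nij2)
    return AgreementScore((total - disagree) / total, "RI")


def adjusted_rand_index(p: Partition, q: Partition) -> AgreementScore:
    """Hubert-Arabie ARI from the contingency table (1 = identical, ~0 = chance)."""
    _check_same_items(p, q)
    table = _contingency(p, q)
    n = p.n
    sum_nij2 = (table * (table - 1) / 2).sum()
    sum_a2 = (table.sum(1) * (table.sum(1) - 1) / 2).sum()
    sum_b2 = (table.sum(0) * (table.sum(0) - 1) / 2).sum()
    total = n_pairs(n)
    expected = sum_a2 * sum_b2 / total
    max_index = (sum_a2 + sum_b2) / 2
    if max_index == expected:  # both partitions degenerate (all-one-cluster etc.)
        return AgreementScore(1.0, "ARI")
    return AgreementScore(float((sum_nij2 - expected) / (max_index - expected)), "ARI")


def _affinity_value(assignments: np.ndarray, S: SimilarityMatrix) -> float:
    iu, ju, s = S.observed_pairs()
    if s.size == 0:
        raise ValueError("affinity needs at least one observed pair")
    same = assignments[iu] == assignments[ju]
    return float(np.where(same, s, 1.0 - s).sum() / s.size)


def affinity(c: Partition, S: SimilarityMatrix) -> AgreementScore:
    """Agreement between a hard clustering and a soft similarity matrix.

    For sparse S the sum runs over observed pairs only and is normalized by
    their number, so alpha stays the mean agreement per judged pair.
    """
    if c.n != S.n:
        raise ValueError("clustering and similarity matrix must cover the same items")
    return AgreementScore(_affinity_value(c.assignments, S), "affinity")


def random_partition(n: int, k: int, rng: np.random.Generator,
                     equal_sizes: bool = False) -> Partition:
    """A random partition of n items into k clusters.

    Default draw assigns each item independently and uniformly (clusters may
    come out empty); ``equal_sizes=True`` instead shuffles a balanced label
    vector.
    """
    if equal_sizes:
        labels = np.arange(n) % k
        rng.shuffle(labels)
    else:
        labels = rng.integers(0, k, size=n)
    return Partition(labels, k)


def soft_ari(c: Partition, S_val: SimilarityMatrix, n_random: int = 1000,
             seed: Optional[int] = None, equal_sizes: bool = False) -> AgreementScore:
    """Chance-corrected affinity against a (possibly soft, sparse) validation matrix.

    ``(RI_m - RI_r) / (1 - RI_r)`` with RI_m the affinity of ``c`` and RI_r
    the mean affinity of ``n_random`` random partitions with the same number
    of non-empty clusters as ``c``.  Seeded and reproducible.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    ri_m = _affinity_value(c.assignments, S_val)
    k_eff = c.n_effective_clusters()
    rng = np.random.default_rng(seed)
    iu, ju, s = S_val.observed_pairs()
    if s.size == 0:
        raise ValueError("validation matrix has no observed pairs")
    # vectorized chance term: one random label matrix, compare per pair
    if equal_sizes:
        labels = np.empty((n_random, c.n), dtype=np.int64)
        base = np.arange(c.n) % k_eff
        for r in range(n_random):
            labels[r] = rng.permutation(base)
    else:
        labels = rng.integers(0, k_eff, size=(n_random, c.n))
    same = labels[:, iu] == labels[:, ju]
    per_run = (np.where(same, s, 1.0 - s)).mean(axis=1)
    ri_r = float(per_run.mean())
    if ri_r >= 1.0 - 1e-12:
        raise ValueError("degenerate chance baseline: RI_r = 1")
    value = (ri_m - ri_r) / (1.0 - ri_r)
    return AgreementScore(value, "softARI", n_random=n_random, seed=seed)


def rand_index_vs_soft(p: Partition, q: Partition) -> float:
    """Identity helper: RI(p, q) computed as affinity(p, comembership(q))."""
    return float(affinity(p, comembership(q)))
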