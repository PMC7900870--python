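"""Build soft similarity matrices from free-sorts or same-different trials.

A single participant's sort induces a binary co-membership matrix; averaging
those across participants gives the soft matrix S that the clusterer is fit
to.  Same-different trials instead populate S sparsely, pair by pair, with
per-pair judgement counts; :func:`densest_subset` extracts a well-observed
sub-sample from such sparse data by greedy maximum connectivity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datatypes import Partition, SimilarityMatrix, TrialRecord, n_pairs

__all__ = [
    "comembership",
    "average_sorts",
    "accumulate_trials",
    "densest_subset",
    "n_pairs",
]


def comembership(partition: Partition) -> SimilarityMatrix:
    """Binary co-membership matrix of a hard partition.

    ``value(i, j) = 1`` iff items i and j share a cluster; fully observed with
    unit counts.
    """
    a = partition.assignments
    values = (a[:, None] == a[None, :]).astype(np.float64)
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix.dense(values)


def average_sorts(sorts: Sequence[Partition]) -> SimilarityMatrix:
    """Mean co-membership over participants: the soft similarity matrix S.

    All partitions must cover the same item set; counts equal the number of
    participants, every pair observed.
    """
    if len(sorts) == 0:
        raise ValueError("need at least one sort")
    n = sorts[0].n
    if any(p.n != n for p in sorts):
        raise ValueError("all sorts must cover the same item set")
    acc = np.zeros((n, n), dtype=np.float64)
    for p in sorts:
        a = p.assignments
        acc += a[:, None] == a[None, :]
    acc /= len(sorts)
    np.fill_diagonal(acc, 0.0)
    counts = np.full((n, n), len(sorts), dtype=np.int64)
    return SimilarityMatrix.dense(acc, counts=counts)


def accumulate_trials(trials: Iterable[TrialRecord], n_items: int) -> SimilarityMatrix:
    """Sparse similarity from same-different trials.

    For each judged pair, ``value = (#same) / (#judgements)``; pairs never
    judged stay unobserved.  Contradictory judgements on a pair average.
    """
    same = np.zeros((n_items, n_items), dtype=np.float64)
    counts = np.zeros((n_items, n_items), dtype=np.int64)
    for t in trials:
        i, j = t.item_i, t.item_j
        if not (0 <= i < n_items and 0 <= j < n_items):
            raise ValueError(f"item id out of range in trial ({i}, {j})")
        same[i, j] += t.same
        same[j, i] += t.same
        counts[i, j] += 1
        counts[j, i] += 1
    observed = counts > 0
    np.fill_diagonal(observed, False)
    values = np.divide(same, counts, out=np.zeros_like(same), where=observed)
    return SimilarityMatrix(values, observed, counts)


def densest_subset(S: SimilarityMatrix, m: int) -> list[int]:
    """Greedy maximum-connectivity sub-sample of a sparse similarity matrix.

    The seed item has the largest number of *unique* observed pairings (ties
    to the lowest item id).  Each subsequent addition is the item with the
    largest count-weighted judgement total against the current sample (again
    lowest-id tie-break).  Deterministic given S and m.
    """
    n = S.n
    if m > n:
        raise ValueError("m cannot exceed the number of items")
    if m < 1:
        raise ValueError("m must be >= 1")
    obs = S.observed
    if not obs.any():
        raise ValueError("similarity matrix has no observed pairs")
    cnt = np.where(obs, S.counts, 0).astype(np.float64)

    degree = obs.sum(axis=1)  # unique pairings
    seed = int(np.argmax(degree))  # argmax takes the lowest index on ties
    chosen = [seed]
    in_sample = np.zeros(n, dtype=bool)
    in_sample[seed] = True
    # running count-weighted connectivity of every candidate to the sample
    conn = cnt[:, seed].copy()
    for _ in range(m - 1):
        conn_masked = np.where(in_sample, -np.inf, conn)
        nxt = int(np.argmax(conn_masked))
        chosen.append(nxt)
        in_sample[nxt] = True
        conn += cnt[:, nxt]
    return chosen
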