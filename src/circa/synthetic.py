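"""Synthetic study data with controlled ground truth.

Emulates the two data-collection paradigms end to end: a planted partition
of items, per-participant free sorts that disagree with the truth at a
controlled rate (each participant reassigns a fraction ``disagreement`` of
items to other clusters, subject to the sorting-task constraints of 3-10
categories with at least two items each), and sparse same-different trials
whose answers flip with probability ``flip_prob`` at a configurable pair
sampling density (uniform, or hub-biased to mimic crowd-sourced sparsity).

Defaults mirror the free-sorting study conditions: 80 items, 20
participants, a six-category truth, category-count bounds 3-10, minimum
cluster size 2.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .datatypes import ParticipantSort, Partition, TrialRecord

__all__ = [
    "GeneratorConfig",
    "sample_truth",
    "simulate_sorts",
    "simulate_trials",
    "default_label_pools",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    ``disagreement`` is the fraction of items each simulated participant
    assigns off-truth; ``flip_prob`` the probability a same-different answer
    is flipped; ``density`` the fraction of item pairs sampled for trials.
    """

    n_items: int = 80
    k_true: int = 6
    size_scheme: str = "equal"  # "equal" | "random"
    min_cluster_size: int = 2
    n_participants: int = 20
    disagreement: float = 0.0
    flip_prob: float = 0.0
    density: float = 1.0
    judgements_per_pair: int = 1
    pair_sampling: str = "uniform"  # "uniform" | "hub"
    category_bounds: Tuple[int, int] = (3, 10)
    enforce_bounds: bool = True
    labels_per_cluster: int = 3
    n_confusable_labels: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("disagreement", "flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_items < self.k_true * self.min_cluster_size:
            raise ValueError("n_items too small for k_true clusters of minimum size")


def sample_truth(config: GeneratorConfig,
                 rng: Optional[np.random.Generator] = None) -> Partition:
    """Planted ground-truth partition honoring the size scheme.

    ``equal`` gives near-equal cluster sizes (differing by at most one);
    ``random`` draws sizes uniformly over compositions with every cluster at
    least ``min_cluster_size``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, k = config.n_items, config.k_true
    if config.size_scheme == "equal":
        sizes = np.full(k, n // k, dtype=np.int64)
        sizes[: n % k] += 1
    elif config.size_scheme == "random":
        spare = n - k * config.min_cluster_size
        cuts = np.sort(rng.integers(0, spare + 1, size=k - 1))
        extras = np.diff(np.concatenate(([0], cuts, [spare])))
        sizes = config.min_cluster_size + extras
    else:
        raise ValueError(f"unknown size scheme {config.size_scheme!r}")
    labels = np.repeat(np.arange(k), sizes)
    rng.shuffle(labels)
    return Partition(labels, k)


def default_label_pools(config: GeneratorConfig) -> List[List[str]]:
    """Disjoint word pools per true cluster, plus optional shared confusables.

    Pool words carry suffix variants of a shared stem so the label-merging
    rule is exercised; confusable words appear in every pool.
    """
    variants = ["", "s", "ing"]
    pools = []
    shared = [f"shared{c}" for c in range(config.n_confusable_labels)]
    for t in range(config.k_true):
        stem = f"group{chr(ord('a') + (t % 26))}{t // 26 if t >= 26 else ''}"
        pool = [stem + variants[v % len(variants)]
                for v in range(max(1, config.labels_per_cluster))]
        pools.append(pool + shared)
    return pools


def _valid_sort(labels: np.ndarray, config: GeneratorConfig) -> bool:
    _, counts = np.unique(labels, return_counts=True)
    lo, hi = config.category_bounds
    return (lo <= counts.size <= hi) and counts.min() >= config.min_cluster_size


def simulate_sorts(truth: Partition, config: GeneratorConfig,
                   rng: Optional[np.random.Generator] = None) -> List[ParticipantSort]:
    """Per-participant sorts at the configured disagreement rate.

    Each participant starts from the truth and reassigns
    ``round(disagreement * n)`` uniformly chosen items to uniformly chosen
    *other* clusters, so the expected off-truth fraction equals the
    disagreement rate.  Sorts violating the category-count bounds are
    resampled (warning); labels are drawn from each cluster's label pool.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, k = truth.n, truth.k
    n_move = int(round(config.disagreement * n))
    pools = default_label_pools(config)
    sorts: List[ParticipantSort] = []
    for _ in range(config.n_participants):
        for attempt in range(200):
            labels = truth.assignments.copy()
            if n_move > 0 and k > 1:
                items = rng.choice(n, size=n_move, replace=False)
                shift = rng.integers(1, k, size=n_move)
                labels[items] = (labels[items] + shift) % k
            if not config.enforce_bounds or _valid_sort(labels, config):
                break
            if attempt == 0:
                warnings.warn("disagreement draw violated category bounds; resampling",
                              stacklevel=2)
        part = Partition(labels, k)
        label_map = {}
        for c in np.unique(labels):
            pool = pools[int(c) % len(pools)]
            n_lab = int(rng.integers(1, min(5, len(pool)) + 1))
            picks = rng.choice(len(pool), size=n_lab, replace=False)
            label_map[int(c)] = [pool[i] for i in picks]
        sorts.append(ParticipantSort(part, label_map))
    return sorts


def _sample_pairs(n: int, config: GeneratorConfig,
                  rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    if config.pair_sampling == "uniform":
        keep = rng.random(iu.size) < config.density
        return iu[keep], ju[keep]
    if config.pair_sampling == "hub":
        # preferential-attachment style: item weights ~ Zipf, pair weight =
        # product, rescaled to the target expected density
        w = 1.0 / (1.0 + np.arange(n, dtype=np.float64))
        rng.shuffle(w)
        pw = w[iu] * w[ju]
        pw *= config.density * iu.size / pw.sum()
        keep = rng.random(iu.size) < np.minimum(pw, 1.0)
        return iu[keep], ju[keep]
    raise ValueError(f"unknown pair sampling {config.pair_sampling!r}")


def simulate_trials(truth: Partition, config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None) -> List[TrialRecord]:
    """Sparse same-different trials with flip noise.

    Pairs are sampled at the configured density; each sampled pair receives
    ``judgements_per_pair`` answers, each equal to the truth's co-membership
    flipped independently with probability ``flip_prob``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    iu, ju = _sample_pairs(truth.n, config, rng)
    pools = default_label_pools(config)
    trials: List[TrialRecord] = []
    a = truth.assignments
    for _ in range(config.judgements_per_pair):
        same_true = a[iu] == a[ju]
        flips = rng.random(iu.size) < config.flip_prob
        answers = same_true ^ flips
        for i, j, ans in zip(iu, ju, answers):
            left_pool = pools[int(a[i]) % len(pools)]
            trials.append(TrialRecord(int(i), int(j), bool(ans),
                                      left_label=left_pool[0]))
    return trials
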