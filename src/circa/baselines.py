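"""Competing methods and the simulation benchmark harness.

``greene_refine`` implements the category-refinement baseline that removes
categories whose within-category "same" proportion falls below 0.75 and
merges category pairs whose between-category proportion exceeds 0.5
(transitively, via connected components).  ``kmedoids_cluster`` and
``spectral_cluster`` adapt standard clusterers to the common contract
``(SimilarityMatrix, k, seed) -> Partition`` so they can be raced against
the affinity clusterer on simulated data by :func:`run_benchmark`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import SpectralClustering

from .agreement import adjusted_rand_index
from .cluster import circa_fit
from .datatypes import Partition, SimilarityMatrix
from .similarity import accumulate_trials
from .synthetic import GeneratorConfig, sample_truth, simulate_trials

__all__ = [
    "CategorySimilarity",
    "greene_refine",
    "circa_cluster",
    "kmedoids_cluster",
    "spectral_cluster",
    "BenchmarkResult",
    "run_benchmark",
]

ClustererContract = Callable[[SimilarityMatrix, int, Optional[int]], Partition]


@dataclass
class CategorySimilarity:
    """Per-category-pair proportion of "same" responses.

    ``proportions[i, j]`` is the fraction of trials pairing categories i and
    j answered "same" (the diagonal holds within-category proportions);
    ``n_trials`` the corresponding trial counts.  NaN marks unjudged pairs.
    """

    categories: List
    proportions: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=np.float64)
        t = np.asarray(self.n_trials, dtype=np.int64)
        k = len(self.categories)
        if p.shape != (k, k) or t.shape != (k, k):
            raise ValueError("proportions and n_trials must be (k, k)")
        if not np.allclose(np.nan_to_num(p), np.nan_to_num(p.T)):
            raise ValueError("proportions must be symmetric")
        valid = ~np.isnan(p)
        if valid.any() and ((p[valid] < -1e-12).any() or (p[valid] > 1 + 1e-12).any()):
            raise ValueError("proportions must lie in [0, 1]")
        self.proportions, self.n_trials = p, t

    @classmethod
    def from_category_trials(cls, trials: Sequence, categories: Mapping) -> "CategorySimilarity":
        """Aggregate item-level same/different trials by category pair.

        ``categories`` maps item id -> category.
        """
        cats = sorted(set(categories.values()))
        idx = {c: i for i, c in enumerate(cats)}
        k = len(cats)
        same = np.zeros((k, k))
        count = np.zeros((k, k), dtype=np.int64)
        for t in trials:
            a, b = idx[categories[t.item_i]], idx[categories[t.item_j]]
            same[a, b] += t.same
            count[a, b] += 1
            if a != b:
                same[b, a] += t.same
                count[b, a] += 1
        with np.errstate(invalid="ignore"):
            prop = np.where(count > 0, same / np.maximum(count, 1), np.nan)
        return cls(cats, prop, count)


def greene_refine(catsim: CategorySimilarity, within_min: float = 0.75,
                  between_max: float = 0.5) -> Dict:
    """Remove weak categories, then merge confusable ones.

    Removal pass: categories with within-category "same" proportion below
    ``within_min`` are dropped (with their images).  Merge pass: surviving
    categories joined by between-category proportions above ``between_max``
    collapse into one refined category per connected component (transitive
    closure on the original, pre-merge proportions).  Returns a map from
    original category to refined category id (None = removed).
    """
    k = len(catsim.categories)
    within = np.diag(catsim.proportions)
    if np.isnan(within).any():
        raise ValueError("every category needs a defined within-category similarity")
    keep = np.flatnonzero(within >= within_min)
    if keep.size == 0:
        raise ValueError("all categories were removed")
    adj = np.zeros((keep.size, keep.size), dtype=bool)
    for a in range(keep.size):
        for b in range(a + 1, keep.size):
            p = catsim.proportions[keep[a], keep[b]]
            if not np.isnan(p) and p > between_max:
                adj[a, b] = adj[b, a] = True
    n_comp, comp = connected_components(adj, directed=False)
    mapping: Dict = {}
    for pos, orig in enumerate(keep):
        mapping[catsim.categories[orig]] = int(comp[pos])
    for orig in range(k):
        if orig not in set(keep.tolist()):
            mapping[catsim.categories[orig]] = None
    return mapping


# ---------------------------------------------------------------------------
# clusterer adapters (common contract: (S, k, seed) -> Partition)


def _dissimilarity(S: SimilarityMatrix, fill: float = 0.5) -> np.ndarray:
    """Distance matrix 1 - s with unobserved pairs imputed at ``fill``."""
    d = np.where(S.observed, 1.0 - S.values, 1.0 - fill)
    np.fill_diagonal(d, 0.0)
    return d


def circa_cluster(S: SimilarityMatrix, k: int, seed: Optional[int] = None,
                  n_restarts: int = 20) -> Partition:
    return circa_fit(S, k, n_restarts=n_restarts, seed=seed).best


def kmedoids_cluster(S: SimilarityMatrix, k: int, seed: Optional[int] = None,
                     max_iter: int = 100) -> Partition:
    """Voronoi-iteration k-medoids on the 1 - s dissimilarity matrix."""
    d = _dissimilarity(S)
    n = S.n
    rng = np.random.default_rng(seed)
    # maxmin (farthest-point) seeding: first medoid random, each further one
    # maximizes its distance to the chosen set - covers well-separated blocks
    medoids = [int(rng.integers(0, n))]
    while len(medoids) < min(k, n):
        mind = d[:, medoids].min(axis=1)
        mind[medoids] = -1.0
        medoids.append(int(np.argmax(mind)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(medoids.size):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(d[:, medoids], axis=1)
    return Partition(labels, k)


def spectral_cluster(S: SimilarityMatrix, k: int, seed: Optional[int] = None) -> Partition:
    """sklearn spectral clustering on the (imputed) precomputed affinity."""
    aff = np.where(S.observed, S.values, 0.5)
    np.fill_diagonal(aff, 1.0)
    model = SpectralClustering(n_clusters=k, affinity="precomputed",
                               random_state=seed, assign_labels="kmeans")
    labels = model.fit_predict(aff)
    return Partition(labels, k)


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class BenchmarkResult:
    """Per-(method, noise, replicate) ARI-to-truth grid with runtimes."""

    records: pd.DataFrame  # columns: method, noise, replicate, ari, seconds

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby(["method", "noise"])["ari"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"mean": "mean_ari", "sem": "se_ari"})


def run_benchmark(
    config: GeneratorConfig,
    methods: Mapping[str, ClustererContract],
    noise_grid: Sequence[float],
    n_replicates: int = 20,
    seed: Optional[int] = None,
) -> BenchmarkResult:
    """Race clustering methods on simulated same-different data.

    For every (noise level, replicate) cell a planted partition is drawn,
    trials are simulated with that flip-noise level, every method clusters
    the accumulated similarity matrix at the true k, and the hard ARI to the
    planted truth is recorded together with the wall-clock fit time.  A
    method raising on an instance is recorded as a missing ARI, not fatal.
    Fully seeded (timings excepted).
    """
    ss = np.random.SeedSequence(seed)
    cell_seeds = (ss.generate_state(len(noise_grid) * n_replicates * 2,
                                    dtype=np.uint32) >> 1).reshape(
        len(noise_grid), n_replicates, 2)
    rows = []
    for gi, noise in enumerate(noise_grid):
        for rep in range(n_replicates):
            cfg = replace(config, flip_prob=float(noise),
                          seed=int(cell_seeds[gi, rep, 0]))
            truth = sample_truth(cfg)
            trials = simulate_trials(truth, cfg)
            S = accumulate_trials(trials, cfg.n_items)
            for mi, (name, method) in enumerate(sorted(methods.items())):
                method_seed = int((cell_seeds[gi, rep, 1] + mi) % (2 ** 31))
                t0 = time.perf_counter()
                try:
                    part = method(S, cfg.k_true, method_seed)
                    ari = float(adjusted_rand_index(part, truth))
                except Exception:
                    ari = np.nan
                elapsed = time.perf_counter() - t0
                rows.append({"method": name, "noise": float(noise),
                             "replicate": rep, "ari": ari, "seconds": elapsed})
    return BenchmarkResult(pd.DataFrame(rows))


def time_to_stationarity(n_grid: Sequence[int], k: int = 4,
                         n_replicates: int = 3, seed: Optional[int] = None,
                         flip_prob: float = 0.1) -> pd.DataFrame:
    """Median single-run ascent time as a function of the number of items.

    Supports the empirical scaling check (runtime grows roughly linearly
    with n at fixed k); returns one row per (n, replicate).
    """
    ss = np.random.SeedSequence(seed)
    seeds = (ss.generate_state(len(n_grid) * n_replicates, dtype=np.uint32) >> 1
             ).reshape(len(n_grid), n_replicates)
    rows = []
    for ni, n in enumerate(n_grid):
        for rep in range(n_replicates):
            cfg = GeneratorConfig(n_items=int(n), k_true=k, flip_prob=flip_prob,
                                  seed=int(seeds[ni, rep]))
            truth = sample_truth(cfg)
            trials = simulate_trials(truth, cfg)
            S = accumulate_trials(trials, cfg.n_items)
            t0 = time.perf_counter()
            circa_fit(S, k, n_restarts=1, seed=int(seeds[ni, rep]))
            rows.append({"n": int(n), "replicate": rep,
                         "seconds": time.perf_counter() - t0})
    return pd.DataFrame(rows)
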