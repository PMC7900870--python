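"""Cross-validated choice of the number of clusters.

Two selection procedures mirroring the two data-collection paradigms:

* free sorts -> leave-one-participant-out CV: for each candidate k, fit the
  clusterer to the averaged similarity matrix of the remaining participants
  and score the hard ARI against the left-out participant's partition;
* same-different trials -> k-fold CV over individual trials: fit on the
  accumulated training-fold similarity matrix and score the soft ARI against
  the left-out fold's sparse matrix.

The trial-fold curve can additionally be smoothed by Nadaraya-Watson kernel
regression with the bandwidth chosen by leave-one-out squared error, and the
number of clusters is then read off the smoothed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agreement import adjusted_rand_index, soft_ari
from .cluster import circa_fit
from .datatypes import ParticipantSort, Partition, SimilarityMatrix, TrialRecord
from .similarity import accumulate_trials, average_sorts

__all__ = [
    "KSelectionResult",
    "select_k_loocv_participants",
    "select_k_kfold_trials",
    "smooth_ari_curve",
    "disagreement_tolerance",
]


@dataclass
class KSelectionResult:
    """Cross-validated ARI-versus-k curve and the chosen number of clusters."""

    k_grid: np.ndarray
    mean_ari: np.ndarray
    se_ari: np.ndarray
    chosen_k: int
    smoothed: Optional[np.ndarray] = None
    bandwidth: Optional[float] = None
    fold_ari: Optional[np.ndarray] = field(default=None, repr=False)  # (folds, k)


def _argmax_smallest_k(k_grid: np.ndarray, scores: np.ndarray) -> int:
    """Argmax with ties resolved to the smallest k (parsimony)."""
    best = np.max(scores)
    return int(k_grid[np.flatnonzero(scores >= best - 1e-12)[0]])


def select_k_loocv_participants(
    sorts: Sequence[ParticipantSort | Partition],
    k_grid: Sequence[int],
    n_restarts: int = 100,
    n_random: int = 1000,
    seed: Optional[int] = None,
) -> KSelectionResult:
    """Choose k by leave-one-participant-out cross-validation.

    For each k and each left-out participant, the clusterer is fit (with
    ``n_restarts`` random initializations) to the averaged similarity matrix
    of the remaining participants and scored by the hard ARI against the
    left-out partition.  ``chosen_k`` maximizes the fold-averaged ARI
    (smallest k on ties).  ``n_random`` is accepted for interface symmetry
    with the trial-fold variant (hard-ARI scoring does not use it).
    """
    partitions = [s.partition if isinstance(s, ParticipantSort) else s for s in sorts]
    if len(partitions) < 2:
        raise ValueError("need at least two participants for LOOCV")
    k_grid = np.asarray(sorted(k_grid), dtype=np.int64)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    n_p = len(partitions)
    ss = np.random.SeedSequence(seed)
    fold_seeds = (ss.generate_state(n_p * k_grid.size, dtype=np.uint32) >> 1).reshape(
        n_p, k_grid.size)
    fold_ari = np.zeros((n_p, k_grid.size))
    for p in range(n_p):
        train = [q for i, q in enumerate(partitions) if i != p]
        S_train = average_sorts(train)
        for ki, k in enumerate(k_grid):
            fit = circa_fit(S_train, int(k), n_restarts=n_restarts,
                            seed=int(fold_seeds[p, ki]))
            fold_ari[p, ki] = float(adjusted_rand_index(fit.best, partitions[p]))
    mean_ari = fold_ari.mean(axis=0)
    se_ari = fold_ari.std(axis=0, ddof=1) / np.sqrt(n_p)
    return KSelectionResult(
        k_grid=k_grid,
        mean_ari=mean_ari,
        se_ari=se_ari,
        chosen_k=_argmax_smallest_k(k_grid, mean_ari),
        fold_ari=fold_ari,
    )


def select_k_kfold_trials(
    trials: Sequence[TrialRecord],
    n_items: int,
    k_grid: Sequence[int],
    n_folds: int = 10,
    n_restarts: int = 100,
    n_random: int = 1000,
    seed: Optional[int] = None,
    smooth: bool = True,
) -> KSelectionResult:
    """Choose k by k-fold cross-validation over individual trials.

    Trials are shuffled once (seeded) and split into ``n_folds`` folds whose
    sizes differ by at most one.  Per fold and candidate k, the clusterer is
    fit to the training folds' accumulated similarity matrix and scored by
    the soft ARI against the left-out fold's sparse matrix (restricted to its
    observed pairs; chance term from ``n_random`` random partitions).  With
    ``smooth=True`` the mean curve is kernel-smoothed and ``chosen_k`` is the
    argmax of the smoothed curve.
    """
    trials = list(trials)
    if len(trials) < n_folds:
        raise ValueError("not enough trials for the requested number of folds")
    k_grid = np.asarray(sorted(k_grid), dtype=np.int64)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    ss = np.random.SeedSequence(seed)
    shuffle_seed, mc_seed = (int(x >> 1) for x in ss.generate_state(2, dtype=np.uint32))
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(trials))
    folds = [order[f::n_folds] for f in range(n_folds)]
    fit_seeds = (np.random.SeedSequence(mc_seed).generate_state(
        n_folds * k_grid.size * 2, dtype=np.uint32) >> 1).reshape(n_folds, k_grid.size, 2)

    fold_ari = np.zeros((n_folds, k_grid.size))
    for f in range(n_folds):
        test_idx = set(folds[f].tolist())
        train = [t for i, t in enumerate(trials) if i not in test_idx]
        test = [trials[i] for i in folds[f]]
        S_train = accumulate_trials(train, n_items)
        S_test = accumulate_trials(test, n_items)
        if S_test.n_observed_pairs() == 0:
            raise ValueError(f"fold {f} has no observed pairs")
        for ki, k in enumerate(k_grid):
            fit = circa_fit(S_train, int(k), n_restarts=n_restarts,
                            seed=int(fit_seeds[f, ki, 0]))
            score = soft_ari(fit.best, S_test, n_random=n_random,
                             seed=int(fit_seeds[f, ki, 1]))
            fold_ari[f, ki] = float(score)
    mean_ari = fold_ari.mean(axis=0)
    se_ari = fold_ari.std(axis=0, ddof=1) / np.sqrt(n_folds)
    result = KSelectionResult(
        k_grid=k_grid,
        mean_ari=mean_ari,
        se_ari=se_ari,
        chosen_k=_argmax_smallest_k(k_grid, mean_ari),
        fold_ari=fold_ari,
    )
    if smooth and k_grid.size >= 3:
        smoothed, bw = smooth_ari_curve(k_grid, mean_ari)
        result.smoothed = smoothed
        result.bandwidth = bw
        result.chosen_k = _argmax_smallest_k(k_grid, smoothed)
    return result


def _nadaraya_watson(x: np.ndarray, y: np.ndarray, h: float,
                     x_eval: np.ndarray) -> np.ndarray:
    w = np.exp(-0.5 * ((x_eval[:, None] - x[None, :]) / h) ** 2)
    return (w @ y) / w.sum(axis=1)


def smooth_ari_curve(k_grid: Sequence[int], mean_ari: Sequence[float],
                     bandwidths: Optional[Sequence[float]] = None):
    """Gaussian-kernel (Nadaraya-Watson) smoothing of the ARI-versus-k curve.

    The kernel scale is picked to minimize the leave-one-out squared error on
    the mean-ARI points, searched over a log-spaced grid spanning roughly the
    grid step up to the grid range.  A constant input curve is degenerate
    (every bandwidth fits equally): the flat curve is returned with the
    smallest bandwidth, and the argmax convention then yields the smallest k.

    Returns ``(smoothed, bandwidth)``.
    """
    x = np.asarray(k_grid, dtype=np.float64)
    y = np.asarray(mean_ari, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 grid points to smooth")
    if bandwidths is None:
        step = np.min(np.diff(np.sort(x)))
        span = x.max() - x.min()
        bandwidths = np.geomspace(0.25 * step, max(span, step), 40)
    best_h, best_err = None, np.inf
    for h in bandwidths:
        pred = np.empty_like(y)
        for i in range(x.size):
            mask = np.ones(x.size, dtype=bool)
            mask[i] = False
            pred[i] = _nadaraya_watson(x[mask], y[mask], h, x[i:i + 1])[0]
        err = float(np.mean((pred - y) ** 2))
        if err < best_err - 1e-15:
            best_err, best_h = err, float(h)
    smoothed = _nadaraya_watson(x, y, best_h, x)
    return smoothed, best_h


def disagreement_tolerance(
    d_grid: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35),
    n_items: int = 48,
    k_true: int = 5,
    n_participants: int = 10,
    k_grid: Sequence[int] = range(2, 9),
    n_restarts: int = 50,
    n_replicates: int = 5,
    seed: Optional[int] = None,
):
    """Highest disagreement rate at which k-selection still recovers the truth.

    For each disagreement level d, ``n_replicates`` synthetic studies are
    simulated (``n_participants`` sorts of a planted ``k_true``-cluster
    partition, each participant reassigning a fraction d of items) and the
    LOOCV selection is run per replicate.  Returns ``(tolerance_percent,
    detail)`` where the tolerance is the largest d (in percent) whose modal
    selected k across replicates equals ``k_true`` (0.0 if none), and
    ``detail`` maps d to the list of selected k values.
    """
    from .synthetic import GeneratorConfig, sample_truth, simulate_sorts

    d_grid = list(d_grid)
    ss = np.random.SeedSequence(seed)
    rep_seeds = (ss.generate_state(len(d_grid) * n_replicates, dtype=np.uint32)
                 >> 1).reshape(len(d_grid), n_replicates)
    detail: dict = {}
    qualifying = []
    for di, d in enumerate(d_grid):
        chosen = []
        for rep in range(n_replicates):
            rep_seed = int(rep_seeds[di, rep])
            cfg = GeneratorConfig(n_items=n_items, k_true=k_true,
                                  n_participants=n_participants,
                                  disagreement=float(d), seed=rep_seed)
            truth = sample_truth(cfg)
            rng = np.random.default_rng(rep_seed)
            sorts = simulate_sorts(truth, cfg, rng=rng)
            res = select_k_loocv_participants(sorts, k_grid,
                                              n_restarts=n_restarts,
                                              seed=rep_seed)
            chosen.append(res.chosen_k)
        values, counts = np.unique(chosen, return_counts=True)
        modal = int(values[np.argmax(counts)])
        detail[float(d)] = chosen
        if modal == k_true:
            qualifying.append(float(d))
    tolerance = 100.0 * max(qualifying) if qualifying else 0.0
    return tolerance, detail
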