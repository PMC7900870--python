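"""Inner loop of the affinity coordinate ascent.

The routine keeps, for every item i and cluster b, the running sums

    M[i, b] = sum of s_ij over observed pairs (i, j) with c_j = b
    O[i, b] = number of observed pairs (i, j) with c_j = b

so the affinity-numerator change for moving item i from cluster a to b is

    delta = (2 M[i, b] - O[i, b]) - (2 M[i, a] - O[i, a])

evaluated in O(1); an accepted move updates one column pair of M and O in
O(n).  Random single-item proposals are accepted iff they *strictly* increase
the affinity.  When n(k-1) consecutive proposals fail, an exhaustive sweep
over all single-item moves either certifies a local maximum (termination) or
applies the best improving move and resumes random proposals.

The loop is compiled with numba when available; the pure-Python fallback is
the very same function (numba reproduces numpy's legacy MT19937 for
``np.random.seed``/``randint``, so the two backends draw identical
proposal streams).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _ascend(sim: np.ndarray, obs: np.ndarray, k: int, seed: int):
    """One coordinate-ascent run from a uniform-random initial clustering.

    Parameters: ``sim`` (n x n float64, 0 where unobserved, zero diagonal),
    ``obs`` (n x n float64 0/1 mask, zero diagonal), cluster bound ``k``,
    RNG seed.  Returns ``(labels, numerator, n_obs_pairs, proposals,
    accepted)``; affinity = numerator / n_obs_pairs.
    """
    np.random.seed(seed)
    n = sim.shape[0]
    c = np.random.randint(0, k, size=n)

    M = np.zeros((n, k))
    O = np.zeros((n, k))
    for i in range(n):
        for j in range(n):
            if obs[i, j] > 0.0:
                M[i, c[j]] += sim[i, j]
                O[i, c[j]] += 1.0

    # affinity numerator over observed upper-triangle pairs
    num = 0.0
    pairs = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i, j] > 0.0:
                pairs += 1.0
                if c[i] == c[j]:
                    num += sim[i, j]
                else:
                    num += 1.0 - sim[i, j]

    proposals = 0
    accepted = 0
    if k == 1 or pairs == 0.0:
        return c, num, pairs, proposals, accepted

    stall_limit = n * (k - 1)
    stall = 0
    while True:
        if stall < stall_limit:
            # random proposal phase
            i = np.random.randint(0, n)
            b = np.random.randint(0, k - 1)
            if b >= c[i]:
                b += 1  # uniform over clusters other than the current one
            proposals += 1
            a = c[i]
            delta = (2.0 * M[i, b] - O[i, b]) - (2.0 * M[i, a] - O[i, a])
            if delta > _EPS:
                accepted += 1
                stall = 0
                num += delta
                c[i] = b
                for j in range(n):
                    if obs[i, j] > 0.0:
                        M[j, a] -= sim[i, j]
                        O[j, a] -= 1.0
                        M[j, b] += sim[i, j]
                        O[j, b] += 1.0
            else:
                stall += 1
        else:
            # exhaustive sweep: certify local maximum or take the best move
            best_delta = 0.0
            best_i = -1
            best_b = -1
            for i in range(n):
                a = c[i]
                base = 2.0 * M[i, a] - O[i, a]
                for b in range(k):
                    if b == a:
                        continue
                    proposals += 1
                    delta = (2.0 * M[i, b] - O[i, b]) - base
                    if delta > best_delta + _EPS:
                        best_delta = delta
                        best_i = i
                        best_b = b
            if best_i < 0 or best_delta <= _EPS:
                break  # verified local maximum
            accepted += 1
            stall = 0
            a = c[best_i]
            num += best_delta
            c[best_i] = best_b
            for j in range(n):
                if obs[best_i, j] > 0.0:
                    M[j, a] -= sim[best_i, j]
                    O[j, a] -= 1.0
                    M[j, best_b] += sim[best_i, j]
                    O[j, best_b] += 1.0

    return c, num, pairs, proposals, accepted


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _ascend = njit(_ascend)
except ImportError:  # pragma: no cover
    pass
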