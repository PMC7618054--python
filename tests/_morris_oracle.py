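"""Independent reference implementation of Morris elementary-effects
statistics and of the spread-maximising trajectory subset.

Deliberately written as plain loops over Python lists with the stdlib
``statistics`` and ``math`` modules, sharing no code with
``atosense.morris``: these functions are the oracle side of dual-route
tests, so they must not reuse the implementation under test.
"""

from __future__ import annotations

import itertools
import math
import statistics


def reference_morris_statistics(trajectories, values, tol=1e-12):
    """mu, mu*, sigma per input dimension from trajectories and outputs.

    ``trajectories``: sequence of (k+1) x k point lists;
    ``values``: matching sequence of length-(k+1) output lists.
    Returns three length-k lists.
    """
    k = len(trajectories[0][0])
    effects = [[] for _ in range(k)]
    for T, y in zip(trajectories, values):
        for a in range(len(T) - 1):
            changed = [j for j in range(k) if abs(T[a + 1][j] - T[a][j]) > tol]
            if len(changed) != 1:
                raise ValueError("trajectory step must change exactly one coordinate")
            j = changed[0]
            step = T[a + 1][j] - T[a][j]
            effects[j].append((y[a + 1] - y[a]) / step)
    mu = [statistics.fmean(e) for e in effects]
    mu_star = [statistics.fmean([abs(v) for v in e]) for e in effects]
    sigma = [statistics.stdev(e) if len(e) > 1 else float("nan") for e in effects]
    return mu, mu_star, sigma


def _pairwise_trajectory_distance(Ta, Tb):
    """Sum of Euclidean distances between every point pair of two trajectories."""
    return sum(math.dist(p, q) for p in Ta for q in Tb)


def reference_best_subset(trajectories, r):
    """Brute-force spread-maximising r-subset (Campolongo criterion)."""
    n = len(trajectories)
    best_val, best_combo = -1.0, None
    for combo in itertools.combinations(range(n), r):
        total = 0.0
        for a, b in itertools.combinations(combo, 2):
            d = _pairwise_trajectory_distance(trajectories[a], trajectories[b])
            total += d * d
        val = math.sqrt(total)
        if val > best_val:
            best_val, best_combo = val, combo
    return set(best_combo), best_val
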