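"""Independent reference computations used as test oracles."""
from __future__ import annotations

import math

import numpy as np


def oracle_best_interval(r, sigma):
    """Exhaustive best-scoring interval by plain nested loops.

    Same contract as the caller's search: maximum of |sum|/(sigma*sqrt(N))
    over every contiguous interval, ties to the longer then leftmost
    interval.
    """
    n = len(r)
    best = -math.inf
    scored = []
    for i in range(n):
        s = 0.0
        for j in range(i, n):
            s += r[j]
            score = abs(s) / (sigma * math.sqrt(j - i + 1))
            scored.append((i, j, score))
            if score > best:
                best = score
    tol = 1e-12 * max(1.0, best)
    candidates = [(i, j, sc) for i, j, sc in scored if sc >= best - tol]
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    return candidates[0]


def oracle_greedy_segments(r, sigma, threshold):
    """Greedy maximal-interval decomposition by explicit recursion."""
    out = []

    def recurse(lo, hi):
        if hi - lo < 1:
            return
        i, j, score = oracle_best_interval(r[lo:hi], sigma)
        if score < threshold:
            return
        out.append((lo + i, lo + j, score))
        recurse(lo, lo + i)
        recurse(lo + j + 1, hi)

    recurse(0, len(r))
    return sorted(out)


def dyadic_instance(rng, n):
    """Random ratio vector on a dyadic grid (multiples of 1/4).

    Dyadic values make every partial sum exactly representable, so two
    correct implementations produce bit-identical interval scores.
    """
    base = rng.integers(-2, 3, size=n) * 0.25
    # sprinkle a few segments with strong signal so calls actually occur
    for _ in range(rng.integers(0, 4)):
        length = int(rng.integers(2, 12))
        start = int(rng.integers(0, max(1, n - length)))
        level = rng.choice([-1.0, -0.75, 0.75, 1.0])
        base[start : start + length] += level
    return base


def oracle_identical_row_groups(matrix):
    """Group rows with identical carrier patterns (brute force)."""
    groups = {}
    for i, row in enumerate(np.asarray(matrix)):
        groups.setdefault(tuple(row.tolist()), []).append(i)
    return sorted((sorted(v) for v in groups.values()), key=lambda g: g[0])


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by hypergeometric-pmf enumeration (scipy pmf)."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    # the factor absorbs pmf rounding (~1e-15) without swallowing the
    # smallest genuine weight gap at N <= 40 (~7e-12 relative)
    return float(pmf[pmf <= p_obs * (1 + 1e-13)].sum())
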