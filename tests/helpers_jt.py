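"""Independent exact-null oracle for the Jonckheere-Terpstra statistic.

Under the no-ties null hypothesis the statistic is the sum of independent
Mann-Whitney U statistics over the cumulative group splits (Harding's
recursion), so its exact distribution is the convolution of exact U null
distributions.  This is computed here from first principles (the classic
two-way count recursion for U), independently of the package's
normal-approximation and permutation code paths.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple:
    """Unnormalized counts of the exact Mann-Whitney U(m, n) null
    distribution over u = 0..m*n (no ties)."""
    if m == 0 or n == 0:
        return (1.0,)
    a = _u_counts(m - 1, n)
    b = _u_counts(m, n - 1)
    out = [0.0] * (m * n + 1)
    for u, v in enumerate(a):
        out[u + n] += v
    for u, v in enumerate(b):
        out[u] += v
    return tuple(out)


def jt_exact_distribution(sizes) -> np.ndarray:
    """Exact null pmf of the JT statistic for the given group sizes
    (support 0 .. sum over i<j of n_i*n_j), assuming no ties."""
    dist = np.array([1.0])
    total = 0
    for n in sizes:
        if total > 0:
            d = np.asarray(_u_counts(total, int(n)))
            dist = np.convolve(dist, d / d.sum())
        total += int(n)
    return dist


def jt_exact_two_sided_p(sizes, jt: float) -> float:
    """Exact two-sided p: doubled smaller inclusive tail, capped at 1."""
    pmf = jt_exact_distribution(sizes)
    support = np.arange(len(pmf))
    lo = pmf[support <= jt + 1e-9].sum()
    hi = pmf[support >= jt - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def compositions(total: int, min_groups: int = 2):
    """All ordered group-size vectors with >= min_groups positive parts."""
    import itertools

    for k in range(min_groups, total + 1):
        for cuts in itertools.combinations(range(1, total), k - 1):
            parts, prev = [], 0
            for c in cuts:
                parts.append(c - prev)
                prev = c
            parts.append(total - prev)
            yield tuple(parts)
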