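"""Independent reference implementations used as test oracles.

These deliberately use the most literal, brute-force formulation of each
statistic so they stay independent of the package's implementation path.
"""

import numpy as np
from scipy.stats import binom


def exact_two_tailed_by_pmf_summation(k, n, p0):
    """Two-tailed binomial p by summing the pmf over each tail and doubling
    the smaller one (capped at 1)."""
    pmf = np.array([binom.pmf(i, n, p0) for i in range(n + 1)])
    lower = pmf[: k + 1].sum()
    upper = pmf[k:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def quadratic_reference_bh(pvals, q):
    """Literal Benjamini-Hochberg step-up definition, O(m^2)-ish."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def grow_blob(size, shape=(16, 16, 16), start=(8, 8, 8)):
    """6-connected component of exactly `size` voxels (breadth-first growth)."""
    vol = np.zeros(shape, dtype=bool)
    frontier = [start]
    seen = set()
    while frontier and len(seen) < size:
        v = frontier.pop(0)
        if v in seen:
            continue
        seen.add(v)
        vol[v] = True
        x, y, z = v
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            frontier.append((x + d[0], y + d[1], z + d[2]))
    assert vol.sum() == size
    return vol
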