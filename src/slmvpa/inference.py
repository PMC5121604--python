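"""Subject-level significance maps: binomial test, FDR, cluster filtering.

Each sphere centre's mean cross-validated accuracy is compared against its
empirical chance level with an exact two-tailed binomial test (doubling
the smaller tail). The resulting p-value map over all admissible centres
of one subject x one scheme is thresholded by Benjamini-Hochberg FDR at
q = 0.01, and surviving voxels are cluster-filtered: only connected
components with strictly more than 20 voxels remain in the final map.

Binomial trial count
--------------------
Repeated random splits reuse the same samples, so the held-out
predictions are far from independent: under the null, the Monte-Carlo
spread of the mean cross-validated accuracy matches a binomial whose
trial count is the *pool size* (the number of distinct samples the test
sets are drawn from), not the summed test count. The default
``n_mode="pool"`` therefore feeds the pool size to the test. Two
alternatives are kept for comparison: ``"total"`` (summed held-out
predictions; markedly anticonservative at these sample sizes) and
``"per_repeat"`` (one repeat's test count; very conservative, heavy
quantization of k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .decoding import CentreMap

__all__ = [
    "binomial_two_tailed_p",
    "accuracy_to_counts",
    "fdr_bh",
    "cluster_filter",
    "infer_subject",
    "SubjectInference",
]

_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


def binomial_two_tailed_p(k: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p-value by doubling the smaller tail.

    p = min(1, 2 * min(P[X <= k], P[X >= k])) for X ~ Binomial(n, p0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    lower = binom.cdf(k, n, p0)
    upper = binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def accuracy_to_counts(mean_accuracy: float, n_test_total: int) -> int:
    """Success count fed to the binomial test: round(accuracy * n)."""
    if not 0.0 <= mean_accuracy <= 1.0:
        raise ValueError("mean_accuracy must be in [0, 1]")
    return int(np.rint(mean_accuracy * n_test_total))


def fdr_bh(pvals, q: float):
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def cluster_filter(
    sig: np.ndarray, min_size: int = 20, connectivity: int = 26
) -> np.ndarray:
    """Remove connected components of size <= min_size (strictly larger
    components survive). Connectivity 6, 18 or 26 (default)."""
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    sig = np.asarray(sig).astype(bool)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[connectivity])
    labels, n = ndimage.label(sig, structure=struct)
    if n == 0:
        return sig.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes > min_size
    keep[0] = False
    return keep[labels]


@dataclass
class SubjectInference:
    """All inference layers for one subject x one scheme.

    ``sig_fdr`` (FDR-thresholded, above-chance, *not* cluster-filtered) is
    what group coincidence maps consume; ``sig_final`` additionally drops
    clusters of <= min_size voxels. ``sig_signed`` keeps two-tailed
    direction: +1 above chance, -1 significantly below.
    """

    shape: tuple[int, int, int]
    centres: np.ndarray
    pvals: np.ndarray          # per centre
    sig_fdr: np.ndarray        # binary volume, above-chance only
    sig_signed: np.ndarray     # int8 volume in {-1, 0, +1}
    sig_final: np.ndarray      # binary volume after cluster filtering
    q: float
    min_cluster: int
    connectivity: int

    def pval_volume(self) -> np.ndarray:
        vol = np.ones(self.shape, dtype=float)
        vol.flat[self.centres] = self.pvals
        return vol

    def cluster_table(self):
        """Surviving clusters of the final map: label, size, peak voxel."""
        import pandas as pd

        struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[self.connectivity])
        labels, n = ndimage.label(self.sig_final, structure=struct)
        pvol = self.pval_volume()
        rows = []
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            flat = np.ravel_multi_index(vox.T, self.shape)
            peak = vox[np.argmin(pvol.flat[flat])]
            rows.append((lab, len(vox), int(peak[0]), int(peak[1]), int(peak[2])))
        return pd.DataFrame(rows, columns=["cluster", "size_voxels", "peak_x", "peak_y", "peak_z"])


def infer_subject(
    acc: CentreMap,
    chance: CentreMap,
    q: float = 0.01,
    min_cluster: int = 20,
    connectivity: int = 26,
    n_mode: str = "pool",
) -> SubjectInference:
    """Binomial + BH-FDR + cluster-extent inference for one accuracy map.

    Per centre: p = two-tailed binomial test of round(accuracy * n)
    successes in n trials at the centre's empirical chance level, with n
    chosen by ``n_mode`` (see module docstring): "pool" (default,
    calibrated), "total", or "per_repeat". BH is applied over all
    centres; the final map keeps above-chance centres only, in clusters
    of more than ``min_cluster`` voxels.
    """
    if acc.shape != chance.shape or not np.array_equal(acc.centres, chance.centres):
        raise ValueError("accuracy and chance maps are not on the same centres/grid")
    if n_mode not in ("pool", "total", "per_repeat"):
        raise ValueError("n_mode must be 'pool', 'total' or 'per_repeat'")
    if n_mode == "pool" and acc.n_pool <= 0:
        raise ValueError("accuracy map does not record its sample pool size")

    pvals = np.empty(len(acc.centres))
    above = np.empty(len(acc.centres), dtype=bool)
    for i in range(len(acc.centres)):
        n = int(acc.n_test_total[i])
        if n_mode == "pool":
            n = int(acc.n_pool)
        elif n_mode == "per_repeat":
            n = max(1, n // max(1, acc.n_repeats))
        p0 = float(np.clip(chance.values[i], 1e-12, 1 - 1e-12))
        k = accuracy_to_counts(float(acc.values[i]), n)
        pvals[i] = binomial_two_tailed_p(k, n, p0)
        above[i] = acc.values[i] > chance.values[i]

    reject = fdr_bh(pvals, q)
    sig_fdr = np.zeros(acc.shape, dtype=bool)
    sig_fdr.flat[acc.centres[reject & above]] = True
    sig_signed = np.zeros(acc.shape, dtype=np.int8)
    sig_signed.flat[acc.centres[reject & above]] = 1
    sig_signed.flat[acc.centres[reject & ~above]] = -1
    sig_final = cluster_filter(sig_fdr, min_size=min_cluster, connectivity=connectivity)
    return SubjectInference(
        shape=acc.shape, centres=acc.centres.copy(), pvals=pvals,
        sig_fdr=sig_fdr, sig_signed=sig_signed, sig_final=sig_final,
        q=q, min_cluster=min_cluster, connectivity=connectivity,
    )
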