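"""Distributional fidelity of augmented cohorts: kernel MMD permutation test.

The squared maximum mean discrepancy between the real and synthetic sample
distributions is estimated with a Gaussian RBF kernel whose bandwidth comes
from the median heuristic on the pooled sample.  Significance is assessed
by randomly re-splitting the pooled samples (label shuffling) and applying
the plus-one-corrected permutation p-value, which is never zero.  A 2-D
UMAP overlay supports qualitative review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """exp(-||x - y||^2 / (2 sigma^2)); accepts vectors or sample matrices."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    d2 = cdist(x, y, "sqeuclidean")
    out = np.exp(-d2 / (2.0 * sigma**2))
    return out if out.size > 1 else float(out[0, 0])


def median_heuristic(samples: np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled sample."""
    samples = np.atleast_2d(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    med = float(np.median(pdist(samples)))
    if med == 0.0:
        raise ValueError("all samples identical: zero bandwidth")
    return med


def mmd2(X: np.ndarray, Y: np.ndarray, sigma: float, unbiased: bool = False) -> float:
    """Squared MMD estimate with an RBF kernel.

    Default is the biased V-statistic (self-pairs included), which is
    nonnegative and exactly zero for identical sample sets; ``unbiased``
    switches to the U-statistic.
    """
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("each sample set needs at least two points")
    kxx = rbf_kernel(X, X, sigma)
    kyy = rbf_kernel(Y, Y, sigma)
    kxy = rbf_kernel(X, Y, sigma)
    if unbiased:
        np.fill_diagonal(kxx, 0.0)
        np.fill_diagonal(kyy, 0.0)
        return (
            kxx.sum() / (m * (m - 1))
            + kyy.sum() / (n * (n - 1))
            - 2.0 * kxy.mean()
        )
    return float(kxx.mean() + kyy.mean() - 2.0 * kxy.mean())


@dataclass
class MMDTestResult:
    mmd2_obs: float
    bandwidth: float
    n_permutations: int
    p_value: float
    seed: int

    def __post_init__(self):
        assert 0.0 < self.p_value <= 1.0
        assert self.p_value >= 1.0 / (self.n_permutations + 1)
        assert self.bandwidth > 0


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    unbiased: bool = False,
) -> MMDTestResult:
    """Two-sample MMD test by label shuffling with plus-one correction.

    The bandwidth is computed once from the pooled samples and reused for
    every permutation; p = (1 + #{MMD_perm >= MMD_obs}) / (n_perm + 1).
    """
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("each group needs at least two samples")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    pooled = np.concatenate([X, Y], axis=0)
    sigma = median_heuristic(pooled)
    K = np.exp(-squareform(pdist(pooled, "sqeuclidean")) / (2 * sigma**2))
    np.fill_diagonal(K, 1.0)

    def stat(idx_x: np.ndarray, idx_y: np.ndarray) -> float:
        kxx = K[np.ix_(idx_x, idx_x)]
        kyy = K[np.ix_(idx_y, idx_y)]
        kxy = K[np.ix_(idx_x, idx_y)]
        if unbiased:
            return (
                (kxx.sum() - m) / (m * (m - 1))
                + (kyy.sum() - n) / (n * (n - 1))
                - 2 * kxy.mean()
            )
        return kxx.mean() + kyy.mean() - 2 * kxy.mean()

    obs = stat(np.arange(m), np.arange(m, m + n))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(m + n)
        if stat(perm[:m], perm[m:]) >= obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return MMDTestResult(float(obs), sigma, n_permutations, float(p), seed)


def embed_2d(real: np.ndarray, synthetic: np.ndarray, seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.1):
    """UMAP overlay of real and synthetic samples.

    Returns (coords, labels): coords is (n_real + n_synth, 2); labels mark
    each row ``real`` or ``synthetic``.
    """
    import umap  # deferred: numba-backed import is slow

    real = np.atleast_2d(real).reshape(len(real), -1)
    synthetic = np.atleast_2d(synthetic).reshape(len(synthetic), -1)
    pooled = np.concatenate([real, synthetic], axis=0)
    if len(pooled) < 10:
        raise ValueError("need at least 10 pooled samples")
    reducer = umap.UMAP(
        n_components=2, random_state=seed,
        n_neighbors=min(n_neighbors, len(pooled) - 1), min_dist=min_dist,
    )
    coords = reducer.fit_transform(pooled)
    labels = ["real"] * len(real) + ["synthetic"] * len(synthetic)
    return np.asarray(coords, float), labels


__all__ = [
    "rbf_kernel",
    "median_heuristic",
    "mmd2",
    "MMDTestResult",
    "permutation_test",
    "embed_2d",
]
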