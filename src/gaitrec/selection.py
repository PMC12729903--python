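"""Cluster-count selection with the Balanced Silhouette Score (BSS).

The silhouette score rewards cohesive, well-separated clusters but, used
alone on growing datasets, favors dumping most samples into one dominant
cluster.  BSS counteracts that by mixing in the Shannon entropy of the
cluster-occupancy distribution:

    BSS = (1 - alpha) * SS_norm + alpha * H_norm,

with SS_norm = (SS + 1)/2 (silhouette's natural range is [-1, 1]) and
H_norm = H / log K (maximum entropy is log K), both in [0, 1].  The weight
alpha defaults to 0.15 and is a fixed hyperparameter, not tuned.  The
selection loop trains the temporal clustering model for each candidate K
over randomly sampled hyperparameter configurations and keeps the K (and
trial) with the highest BSS, breaking ties toward smaller K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dtc import DTCConfig, DTCModel, train_dtc
from .layout import CohortTensor


def silhouette_coefficient(i: int, labels: np.ndarray, distances: np.ndarray) -> float:
    """SC(i) = (b(i) - a(i)) / max(a(i), b(i)) on a precomputed matrix.

    a(i) excludes the self-distance; b(i) is the smallest mean distance to
    another cluster.  A sample alone in its cluster scores 0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    own = labels[i]
    same = (labels == own) & (np.arange(len(labels)) != i)
    if not same.any():
        return 0.0
    a = distances[i, same].mean()
    b = min(distances[i, labels == c].mean() for c in uniq if c != own)
    return float((b - a) / max(a, b))


def silhouette_score(labels: np.ndarray, distances: np.ndarray) -> float:
    """Mean silhouette coefficient over all samples."""
    return float(
        np.mean([silhouette_coefficient(i, labels, distances) for i in range(len(labels))])
    )


def shannon_entropy(labels: np.ndarray, K: int) -> float:
    """Occupancy entropy in nats; empty clusters contribute zero."""
    labels = np.asarray(labels)
    if len(labels) < 1:
        raise ValueError("need at least one sample")
    counts = np.bincount(labels, minlength=K).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


@dataclass
class BSSResult:
    K: int
    SS: float
    H: float
    SS_norm: float
    H_norm: float
    alpha: float
    BSS: float
    trial_id: int | None = None
    hyperparams: dict | None = None

    def __post_init__(self):
        assert abs(self.BSS - ((1 - self.alpha) * self.SS_norm + self.alpha * self.H_norm)) < 1e-12
        for v in (self.SS_norm, self.H_norm, self.BSS):
            assert -1e-12 <= v <= 1 + 1e-12


def balanced_silhouette(SS: float, H: float, K: int, alpha: float = 0.15) -> BSSResult:
    """Combine silhouette and occupancy entropy into the BSS index."""
    if K < 2:
        raise ValueError("K must be >= 2 (entropy normalization undefined)")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    ss_norm = (SS + 1.0) / 2.0
    h_norm = H / np.log(K)
    bss = (1 - alpha) * ss_norm + alpha * h_norm
    return BSSResult(K, SS, H, ss_norm, h_norm, alpha, bss)


def score_model(model: DTCModel, alpha: float = 0.15) -> BSSResult:
    """BSS of a fitted clustering model on its own latent geometry.

    Degenerate single-cluster solutions score SS_norm = 0 and H_norm = 0
    (BSS = 0) rather than erroring, so the selection loop can rank them.
    """
    K = model.config.K
    labels = model.labels
    if len(np.unique(labels)) < 2:
        res = BSSResult(K, -1.0, 0.0, 0.0, 0.0, alpha, 0.0)
        return res
    D = squareform(pdist(model.latents))
    ss = silhouette_score(labels, D)
    h = shannon_entropy(labels, K)
    return balanced_silhouette(ss, h, K, alpha)


DEFAULT_SEARCH_SPACE = {
    "lr_tae": (5e-3, 1e-2),  # log-uniform
    "lr_cluster": (5e-4, 5e-3),  # log-uniform
    "pool_size": (2, 4, 6, 8),
}


def _sample_config(K: int, space: dict, base: DTCConfig, rng: np.random.Generator
                   ) -> DTCConfig:
    lo, hi = space.get("lr_tae", DEFAULT_SEARCH_SPACE["lr_tae"])
    lr_tae = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = space.get("lr_cluster", DEFAULT_SEARCH_SPACE["lr_cluster"])
    lr_cluster = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    pool = int(rng.choice(space.get("pool_size", DEFAULT_SEARCH_SPACE["pool_size"])))
    return DTCConfig(
        K=K,
        conv_filters=base.conv_filters,
        kernel_size=base.kernel_size,
        pool_size=pool,
        lstm_hidden_1=base.lstm_hidden_1,
        lstm_hidden_2=base.lstm_hidden_2,
        lr_tae=lr_tae,
        lr_cluster=lr_cluster,
        epochs_tae=base.epochs_tae,
        epochs_cluster=base.epochs_cluster,
        linkage_method=base.linkage_method,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class SelectionResult:
    table: pd.DataFrame  # one row per (K, trial)
    summary: pd.DataFrame  # per-K best rows
    best_K: int
    best_model: DTCModel
    best_result: BSSResult


def select_k(
    cohort: CohortTensor,
    k_range=range(3, 11),
    n_trials: int = 20,
    search_space: dict | None = None,
    alpha: float = 0.15,
    base_config: DTCConfig | None = None,
    seed: int = 0,
    setting: str = "augmented",
) -> SelectionResult:
    """Train DTC for each K over sampled hyperparameters, rank by best BSS.

    Ties on the per-K maximum BSS break toward smaller K (parsimony).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = search_space or DEFAULT_SEARCH_SPACE
    if not set(space) <= set(DEFAULT_SEARCH_SPACE):
        raise ValueError(f"unknown search-space keys: {set(space) - set(DEFAULT_SEARCH_SPACE)}")
    base = base_config or DTCConfig()
    rng = np.random.default_rng(seed)
    rows = []
    best = None  # (bss, K, model, result)
    for K in k_range:
        for trial in range(n_trials):
            cfg = _sample_config(K, space, base, rng)
            model = train_dtc(cohort, cfg)
            res = score_model(model, alpha)
            res.trial_id = trial
            res.hyperparams = {
                "lr_tae": cfg.lr_tae, "lr_cluster": cfg.lr_cluster,
                "pool_size": cfg.pool_size, "seed": cfg.seed,
            }
            rows.append(
                {
                    "setting": setting, "K": K, "trial": trial, "BSS": res.BSS,
                    "SS": res.SS, "H": res.H, "SS_norm": res.SS_norm,
                    "H_norm": res.H_norm, **res.hyperparams,
                }
            )
            if best is None or res.BSS > best[0] + 1e-12 or (
                abs(res.BSS - best[0]) <= 1e-12 and K < best[1]
            ):
                best = (res.BSS, K, model, res)
    table = pd.DataFrame(rows)
    summary = (
        table.loc[table.groupby("K")["BSS"].idxmax()]
        .reset_index(drop=True)[["setting", "K", "BSS", "SS", "H", "SS_norm", "H_norm"]]
    )
    return SelectionResult(table, summary, best[1], best[2], best[3])


__all__ = [
    "silhouette_coefficient",
    "silhouette_score",
    "shannon_entropy",
    "BSSResult",
    "balanced_silhouette",
    "score_model",
    "select_k",
    "SelectionResult",
    "DEFAULT_SEARCH_SPACE",
]
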