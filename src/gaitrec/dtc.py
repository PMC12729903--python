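"""Deep Temporal Clustering: temporal autoencoder + Student-t cluster layer.

The encoder compresses each 8x600 patient tensor along the week axis —
Conv1D with Leaky ReLU, max-pooling (pool size from {2, 4, 6, 8}), then two
bidirectional LSTMs with hidden sizes 50 and 1 — into a short latent
sequence Z.  A decoder (upsampling followed by convolution) reconstructs
the input so that Z stays informative.  Cluster membership is a Student-t
soft assignment q_ij on latent distances; centroids are initialized by
hierarchical (complete-linkage) clustering of pretrained latents and the
whole model then trains end-to-end against reconstruction MSE plus the KL
divergence between q and the sharpened target distribution p (the standard
deep-embedded-clustering target p_ij = (q_ij^2/f_j) / sum_j' (q_ij'^2/f_j'),
refreshed every epoch).  Hard labels are argmax_j q_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .layout import CohortTensor
from .nn import (
    Adam,
    BiLSTM,
    Conv1d,
    Module,
    Tensor,
    clip_grad_norm,
    max_pool_time,
    upsample_time,
)

_EPS = 1e-12  # floor inside logs of the clustering KL


@dataclass
class DTCConfig:
    K: int = 6
    conv_filters: int = 32
    kernel_size: int = 5
    pool_size: int = 6
    lstm_hidden_1: int = 50
    lstm_hidden_2: int = 1
    lr_tae: float = 6.761e-3
    lr_cluster: float = 5.534e-4
    epochs_tae: int = 150
    epochs_cluster: int = 100
    linkage_method: str = "complete"
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.lr_tae <= 0 or self.lr_cluster <= 0:
            raise ValueError("learning rates must be positive")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean squared error over all entries."""
    X, Xhat = np.asarray(X, float), np.asarray(Xhat, float)
    if X.shape != Xhat.shape:
        raise ValueError("shapes must agree")
    return float(((X - Xhat) ** 2).mean())


def soft_assign(Z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student-t soft assignment: q_ij ∝ (1 + ||z_i - mu_j||^2)^-1."""
    Z = np.atleast_2d(Z)
    centroids = np.atleast_2d(centroids)
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    q = 1.0 / (1.0 + d2)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target p_ij = (q_ij^2 / f_j) / sum_j'(q_ij'^2 / f_j')."""
    Q = np.atleast_2d(Q)
    f = Q.sum(axis=0)
    w = Q**2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_clustering_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) summed over samples, with an epsilon floor inside logs."""
    P, Q = np.atleast_2d(P), np.atleast_2d(Q)
    return float((P * (np.log(P + _EPS) - np.log(Q + _EPS))).sum())


def init_centroids(Z_all: np.ndarray, K: int, method: str = "complete") -> np.ndarray:
    """Agglomerative initialization: cut the dendrogram at K, mean per cluster."""
    Z_all = np.atleast_2d(Z_all)
    n = len(Z_all)
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if K == 1:
        return Z_all.mean(axis=0, keepdims=True)
    labels = fcluster(linkage(Z_all, method=method), t=K, criterion="maxclust")
    return np.stack([Z_all[labels == c].mean(axis=0) for c in np.unique(labels)])


class TemporalAutoencoder(Module):
    def __init__(self, d_in: int, T: int, cfg: DTCConfig, rng: np.random.Generator):
        self.T = T
        self.pool = min(cfg.pool_size, T)
        self.T_latent = -(-T // self.pool)
        self.conv = Conv1d(d_in, cfg.conv_filters, cfg.kernel_size, rng)
        self.lstm1 = BiLSTM(cfg.conv_filters, cfg.lstm_hidden_1, rng)
        self.lstm2 = BiLSTM(2 * cfg.lstm_hidden_1, cfg.lstm_hidden_2, rng)
        self.latent_width = 2 * cfg.lstm_hidden_2
        self.dec_conv1 = Conv1d(self.latent_width, cfg.conv_filters, cfg.kernel_size, rng)
        self.dec_conv2 = Conv1d(cfg.conv_filters, d_in, cfg.kernel_size, rng)

    def encode(self, x: Tensor) -> Tensor:
        h = self.conv(x).leaky_relu(0.2)
        h = max_pool_time(h, self.pool)
        h = self.lstm1(h)
        return self.lstm2(h)

    def decode(self, z: Tensor) -> Tensor:
        h = upsample_time(z, self.pool, self.T)
        h = self.dec_conv1(h).leaky_relu(0.2)
        return self.dec_conv2(h)


@dataclass
class DTCModel:
    """Fitted model: hard labels, latents, soft assignments, centroids."""

    config: DTCConfig
    labels: np.ndarray
    latents: np.ndarray  # (N, T_latent * latent_width), flattened
    soft: np.ndarray  # (N, K)
    centroids: np.ndarray
    tae_loss_history: list[float] = field(default_factory=list)
    joint_loss_history: list[float] = field(default_factory=list)
    _tae: TemporalAutoencoder | None = None
    _mu_x: np.ndarray | None = None
    _sd_x: np.ndarray | None = None

    def encode(self, values: np.ndarray) -> np.ndarray:
        x = (values - self._mu_x) / self._sd_x
        z = self._tae.encode(Tensor(x))
        return z.data.reshape(len(values), -1)

    def predict(self, values: np.ndarray) -> np.ndarray:
        q = soft_assign(self.encode(values), self.centroids)
        return q.argmax(axis=1)

    def majority_vote_patient_labels(self, patient_ids: list[str]) -> dict[str, int]:
        """Aggregate per-sample labels over a patient's synthetic replicates."""
        base = [pid.split("_syn")[0] for pid in patient_ids]
        out: dict[str, int] = {}
        for b in dict.fromkeys(base):
            votes = self.labels[[i for i, x in enumerate(base) if x == b]]
            counts = np.bincount(votes, minlength=self.config.K)
            out[b] = int(counts.argmax())
        return out


def _soft_assign_t(zf: Tensor, cent: Tensor) -> Tensor:
    n, D = zf.shape
    K = cent.shape[0]
    z2 = (zf**2).sum(axis=1, keepdims=True)  # (n, 1)
    c2 = (cent**2).sum(axis=1).reshape(1, K)  # (1, K)
    d2 = z2 + c2 - (zf @ cent.T) * 2.0
    q = (d2 + 1.0) ** -1.0
    return q / q.sum(axis=1, keepdims=True)


def train_dtc(cohort: CohortTensor, config: DTCConfig | None = None) -> DTCModel:
    """Two-phase training: autoencoder pretrain, then joint clustering."""
    cfg = config or DTCConfig()
    if not cohort.is_complete():
        raise ValueError("cohort must be complete (impute first)")
    n, T, d = cohort.values.shape
    if cfg.K > n:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(cfg.seed)
    mu_x = cohort.values.mean(axis=0)
    sd_x = cohort.values.std(axis=0)
    sd_x[sd_x < 1e-8] = 1.0
    x = (cohort.values - mu_x) / sd_x

    tae = TemporalAutoencoder(d, T, cfg, rng)
    params = tae.parameters()
    opt = Adam(params, lr=cfg.lr_tae)
    xt = Tensor(x)
    tae_hist = []
    for _ in range(cfg.epochs_tae):
        z = tae.encode(xt)
        xhat = tae.decode(z)
        loss = ((xhat - xt) ** 2).mean()
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(params, cfg.grad_clip)
        opt.step()
        tae_hist.append(float(loss.data))

    z0 = tae.encode(xt).data.reshape(n, -1)
    centroids = init_centroids(z0, cfg.K, cfg.linkage_method)
    cent = Tensor(centroids, requires_grad=True)
    joint_params = params + [cent]
    opt2 = Adam(joint_params, lr=cfg.lr_cluster)
    joint_hist = []
    for _ in range(cfg.epochs_cluster):
        z = tae.encode(xt)
        zf = z.reshape(n, z.data.shape[1] * z.data.shape[2])
        q = _soft_assign_t(zf, cent)
        p = target_distribution(q.data)
        xhat = tae.decode(z)
        rec = ((xhat - xt) ** 2).mean()
        clus = -(Tensor(p) * (q + _EPS).log()).sum() + float(
            (p * np.log(p + _EPS)).sum()
        )
        loss = rec + clus
        opt2.zero_grad()
        loss.backward()
        clip_grad_norm(joint_params, cfg.grad_clip)
        opt2.step()
        joint_hist.append(float(loss.data))

    z_final = tae.encode(xt).data.reshape(n, -1)
    q_final = soft_assign(z_final, cent.data)
    return DTCModel(
        config=cfg,
        labels=q_final.argmax(axis=1),
        latents=z_final,
        soft=q_final,
        centroids=cent.data.copy(),
        tae_loss_history=tae_hist,
        joint_loss_history=joint_hist,
        _tae=tae,
        _mu_x=mu_x,
        _sd_x=sd_x,
    )


__all__ = [
    "DTCConfig",
    "DTCModel",
    "TemporalAutoencoder",
    "reconstruction_loss",
    "soft_assign",
    "target_distribution",
    "kl_clustering_loss",
    "init_centroids",
    "train_dtc",
]
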