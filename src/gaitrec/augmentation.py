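"""Generative augmentation of trajectory cohorts.

Two generators over complete (post-imputation) 8x600 patient tensors:

- a time-series variational autoencoder (primary): convolutional encoder
  over the week axis to a low-dimensional Gaussian latent, reparameterized
  sampling, convolutional decoder; trained with reconstruction + KL loss;
- a denoising-diffusion generator (alternative): a noise schedule
  progressively corrupts sequences toward N(0, I) and a convolutional
  network trained to predict the injected noise runs the reverse chain.

Augmentation at ratio r pairs each real patient with r synthetic samples.
For the VAE the default draws latents from the source patient's posterior
(mu_i + sigma_i * eps), which keeps each synthetic sample a plausible
variation of a real recovery course; unconditional prior sampling is also
available.  The diffusion generator samples unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import CohortTensor
from .nn import Adam, Conv1d, Dense, Module, Tensor, clip_grad_norm, concatenate


def reparameterize(mu: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """z = mu + sigma * epsilon with strictly positive sigma."""
    mu, sigma, epsilon = map(np.asarray, (mu, sigma, epsilon))
    if not (sigma > 0).all():
        raise ValueError("sigma must be positive")
    return mu + sigma * epsilon


def gaussian_kl(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL(N(mu, diag sigma^2) || N(0, I)), summed over dimensions."""
    mu, sigma = np.asarray(mu, float), np.asarray(sigma, float)
    return float(0.5 * (mu**2 + sigma**2 - 2 * np.log(sigma) - 1.0).sum())


@dataclass
class VAEConfig:
    latent_dim: int = 2
    learning_rate: float = 1e-4
    epochs: int = 1000
    batch_size: int = 64
    n_layers: int = 3
    conv_filters: int = 32
    kernel_size: int = 5
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1 or min(
            self.learning_rate, self.epochs, self.batch_size, self.n_layers
        ) <= 0:
            raise ValueError("VAEConfig fields must be positive")


class _ConvStack(Module):
    def __init__(self, c_in, c_hidden, c_out, n_layers, kernel, rng, final_linear=True):
        layers = []
        c = c_in
        for i in range(n_layers - 1):
            layers.append(Conv1d(c, c_hidden, kernel, rng))
            c = c_hidden
        layers.append(Conv1d(c, c_out, kernel, rng))
        self.layers = layers
        self.final_linear = final_linear

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or not self.final_linear:
                x = x.leaky_relu(0.2)
        return x


class TimeSeriesVAE:
    """Convolutional VAE over (n_weeks, total_length) patient tensors."""

    def __init__(self, config: VAEConfig | None = None):
        self.config = config or VAEConfig()
        self._fitted = False

    def _standardize(self, values: np.ndarray):
        self.mu_x_ = values.mean(axis=0)
        self.sd_x_ = values.std(axis=0)
        self.sd_x_[self.sd_x_ < 1e-8] = 1.0

    def _encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc_conv_(x)
        n = h.shape[0]
        flat = h.reshape(n, self.T_ * self.config.conv_filters)
        stats = self.enc_head_(flat)
        mu = stats[:, : self.config.latent_dim]
        log_var = stats[:, self.config.latent_dim :].tanh() * 10.0  # keep sigma in e^[-5, 5]
        sigma = (log_var * 0.5).exp()
        return mu, sigma

    def _decode_t(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        h = self.dec_head_(z).leaky_relu(0.2)
        h = h.reshape(n, self.T_, self.config.conv_filters)
        return self.dec_conv_(h)

    def fit(self, cohort: CohortTensor) -> "TimeSeriesVAE":
        if not cohort.is_complete():
            raise ValueError(
                "cohort contains missing weeks; run the imputation stage first"
            )
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.T_, self.d_ = cohort.values.shape[1:]
        self._standardize(cohort.values)
        x = (cohort.values - self.mu_x_) / self.sd_x_
        F = cfg.conv_filters
        self.enc_conv_ = _ConvStack(self.d_, F, F, cfg.n_layers, cfg.kernel_size, rng,
                                    final_linear=False)
        self.enc_head_ = Dense(self.T_ * F, 2 * cfg.latent_dim, rng)
        self.dec_head_ = Dense(cfg.latent_dim, self.T_ * F, rng)
        self.dec_conv_ = _ConvStack(F, F, self.d_, cfg.n_layers, cfg.kernel_size, rng)
        params = (
            self.enc_conv_.parameters() + self.enc_head_.parameters()
            + self.dec_head_.parameters() + self.dec_conv_.parameters()
        )
        opt = Adam(params, lr=cfg.learning_rate)
        n = x.shape[0]
        self.loss_history_: list[float] = []
        self.recon_history_: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = ep_rec = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = Tensor(x[idx])
                mu, sigma = self._encode_t(xb)
                eps = Tensor(rng.standard_normal(mu.shape))
                z = mu + sigma * eps
                xhat = self._decode_t(z)
                rec = ((xhat - xb) ** 2).sum() * (1.0 / len(idx))
                kl = (mu**2 + sigma**2 - (sigma**2 + 1e-12).log() - 1.0).sum() * (
                    0.5 / len(idx)
                )
                loss = rec + kl
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(params, cfg.grad_clip)
                opt.step()
                ep_loss += float(loss.data) * len(idx)
                ep_rec += float(rec.data) * len(idx)
            self.loss_history_.append(ep_loss / n)
            self.recon_history_.append(ep_rec / n)
        self._fitted = True
        return self

    def encode(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        x = (values - self.mu_x_) / self.sd_x_
        mu, sigma = self._encode_t(Tensor(x))
        return mu.data, sigma.data

    def decode(self, z: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        out = self._decode_t(Tensor(np.atleast_2d(z)))
        return out.data * self.sd_x_ + self.mu_x_

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Unconditional samples: z ~ N(0, I) decoded to (n, T, d)."""
        if n <= 0:
            raise ValueError("n must be positive")
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.latent_dim))
        return self.decode(z)

    def augment(self, cohort: CohortTensor, ratio: int, seed: int = 0) -> np.ndarray:
        """Posterior-conditional synthetic samples, source-major order.

        Returns (N*ratio, T, d): for each real sample i, ``ratio`` decodes
        of z = mu_i + sigma_i * eps.
        """
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        rng = np.random.default_rng(seed)
        mu, sigma = self.encode(cohort.values)
        out = []
        for i in range(cohort.n_patients):
            eps = rng.standard_normal((ratio, self.config.latent_dim))
            z = reparameterize(mu[i], np.maximum(sigma[i], 1e-12), eps)
            out.append(self.decode(z))
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Denoising diffusion generator
# ---------------------------------------------------------------------------


def linear_beta_schedule(n_steps: int = 100, beta_start: float = 1e-4,
                         beta_end: float = 0.02) -> np.ndarray:
    return np.linspace(beta_start, beta_end, n_steps)


@dataclass
class DiffusionConfig:
    n_steps: int = 100
    beta_schedule: np.ndarray | None = None
    learning_rate: float = 1e-3
    epochs: int = 400
    conv_filters: int = 32
    kernel_size: int = 5
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.beta_schedule is None:
            self.beta_schedule = linear_beta_schedule(self.n_steps)
        self.beta_schedule = np.asarray(self.beta_schedule, float)
        if len(self.beta_schedule) != self.n_steps:
            raise ValueError("beta_schedule length must equal n_steps")
        if not ((self.beta_schedule > 0) & (self.beta_schedule < 1)).all():
            raise ValueError("beta values must lie in (0, 1)")
        if (np.diff(self.beta_schedule) < 0).any():
            raise ValueError("beta schedule must be non-decreasing")


def forward_noising(x0: np.ndarray, t: int, schedule: np.ndarray,
                    epsilon: np.ndarray) -> np.ndarray:
    """Closed-form marginal of the stepwise Gaussian corruption.

    x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps, abar_t = prod(1 - beta_s)
    for s <= t (t is 1-based).
    """
    schedule = np.asarray(schedule, float)
    if not 1 <= t <= len(schedule):
        raise ValueError(f"t must be in [1, {len(schedule)}]")
    abar = float(np.prod(1.0 - schedule[:t]))
    return np.sqrt(abar) * np.asarray(x0) + np.sqrt(1.0 - abar) * np.asarray(epsilon)


class DiffusionGenerator:
    """DDPM-style generator with an epsilon-predicting conv network.

    The reverse kernel's variance is fixed to beta_t * I; the network input
    is the noisy sequence with a sinusoidal embedding of t appended as
    extra channels.
    """

    def __init__(self, config: DiffusionConfig | None = None):
        self.config = config or DiffusionConfig()
        self._fitted = False

    def _net(self, xt: np.ndarray, t_frac: np.ndarray) -> Tensor:
        n, T, _ = xt.shape
        emb = np.stack(
            [t_frac, np.sin(2 * np.pi * t_frac), np.cos(2 * np.pi * t_frac)], axis=1
        )  # (n, 3)
        emb = np.broadcast_to(emb[:, None, :], (n, T, 3))
        x_in = concatenate([Tensor(xt), Tensor(emb.copy())], axis=-1)
        return self.eps_net_(x_in)

    def fit(self, cohort: CohortTensor) -> "DiffusionGenerator":
        if not cohort.is_complete():
            raise ValueError(
                "cohort contains missing weeks; run the imputation stage first"
            )
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.T_, self.d_ = cohort.values.shape[1:]
        self.mu_x_ = cohort.values.mean(axis=0)
        self.sd_x_ = cohort.values.std(axis=0)
        self.sd_x_[self.sd_x_ < 1e-8] = 1.0
        x0 = (cohort.values - self.mu_x_) / self.sd_x_
        self.eps_net_ = _ConvStack(
            self.d_ + 3, cfg.conv_filters, self.d_, 3, cfg.kernel_size, rng
        )
        params = self.eps_net_.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        n = x0.shape[0]
        abar = np.cumprod(1.0 - cfg.beta_schedule)
        self.loss_history_: list[float] = []
        for _ in range(cfg.epochs):
            t = rng.integers(1, cfg.n_steps + 1, size=n)
            eps = rng.standard_normal(x0.shape)
            a = abar[t - 1][:, None, None]
            xt = np.sqrt(a) * x0 + np.sqrt(1 - a) * eps
            pred = self._net(xt, t / cfg.n_steps)
            loss = ((pred - Tensor(eps)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            self.loss_history_.append(float(loss.data))
        self._fitted = True
        return self

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        cfg = self.config
        rng = np.random.default_rng(seed)
        beta = cfg.beta_schedule
        alpha = 1.0 - beta
        abar = np.cumprod(alpha)
        x = rng.standard_normal((n, self.T_, self.d_))
        for t in range(cfg.n_steps, 0, -1):
            eps_hat = self._net(x, np.full(n, t / cfg.n_steps)).data
            mean = (x - beta[t - 1] / np.sqrt(1 - abar[t - 1]) * eps_hat) / np.sqrt(
                alpha[t - 1]
            )
            if t > 1:
                x = mean + np.sqrt(beta[t - 1]) * rng.standard_normal(x.shape)
            else:
                x = mean
        return x * self.sd_x_ + self.mu_x_

    def augment(self, cohort: CohortTensor, ratio: int, seed: int = 0) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("generator is not trained")
        return self.sample(cohort.n_patients * ratio, seed=seed)


def augment_cohort(cohort: CohortTensor, generator, ratio: int = 5,
                   seed: int = 0) -> CohortTensor:
    """Combine N real samples with N*ratio synthetic ones.

    Synthetic samples are source-major (sample i's replicates follow it in
    blocks), inherit the source's week labels and archetype id, carry ids
    ``<source>_syn<j>`` and provenance ``synthetic``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    synth = np.asarray(generator.augment(cohort, ratio, seed=seed))
    n = cohort.n_patients
    if synth.shape != (n * ratio, cohort.n_weeks, cohort.values.shape[2]):
        raise ValueError("generator returned wrong shape")
    if not np.isfinite(synth).all():
        raise ValueError("generator returned non-finite values")
    values = np.concatenate([cohort.values, synth], axis=0)
    mask = np.ones((n * (1 + ratio), cohort.n_weeks), dtype=int)
    ids = list(cohort.patient_ids) + [
        f"{cohort.patient_ids[i]}_syn{j}" for i in range(n) for j in range(ratio)
    ]
    arch = cohort.archetype_ids
    arch_out = None
    if arch is not None:
        arch_out = list(arch) + [arch[i] for i in range(n) for _ in range(ratio)]
    prov = ["real"] * n + ["synthetic"] * (n * ratio)
    return CohortTensor(
        values, mask, ids, tuple(cohort.weeks), cohort.layout,
        archetype_ids=arch_out, provenance=prov,
    )


__all__ = [
    "reparameterize",
    "gaussian_kl",
    "VAEConfig",
    "TimeSeriesVAE",
    "DiffusionConfig",
    "DiffusionGenerator",
    "linear_beta_schedule",
    "forward_noising",
    "augment_cohort",
]
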