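"""Bidirectional recurrent imputation of week-level missing trajectories.

Missingness in this cohort is week-level: a patient either has a complete
600-dimensional trajectory vector for an assessment week or nothing at all.
The imputer runs a gated recurrent estimator over the 8-week sequence in
both directions.  At every step the next week's vector is predicted from
the running hidden state by a linear read-out, observed weeks are merged
with estimates through the complement operation, and training minimizes the
reconstruction error on observed entries only — self-supervised by hiding a
fraction of the observed weeks each epoch — plus a forward/backward
agreement penalty at missing steps.  The final imputation for a missing
week is the average of the forward and backward estimates; observed weeks
pass through bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .layout import CohortTensor
from .nn import Adam, Dense, GRUCell, Module, Tensor, clip_grad_norm, concatenate


def complement(X: np.ndarray, M: np.ndarray, Xhat: np.ndarray) -> np.ndarray:
    """Merge observed values with estimates: M*X + (1-M)*Xhat."""
    X, M, Xhat = np.asarray(X), np.asarray(M), np.asarray(Xhat)
    if not np.isin(M, (0, 1)).all():
        raise ValueError("mask must be binary")
    if X.shape != Xhat.shape:
        raise ValueError("X and Xhat shapes must agree")
    return np.where(M == 1, X, Xhat)


def masked_reconstruction_loss(X: np.ndarray, Xhat: np.ndarray, M: np.ndarray) -> float:
    """Sum of squared errors over observed entries only."""
    X, Xhat, M = np.asarray(X, float), np.asarray(Xhat, float), np.asarray(M, float)
    if X.shape != Xhat.shape:
        raise ValueError("shapes must agree")
    return float((M * (X - Xhat) ** 2).sum())


@dataclass
class ImputerConfig:
    hidden_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 150
    artificial_mask_fraction: float = 0.1
    consistency_weight: float = 0.1
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.artificial_mask_fraction < 1:
            raise ValueError("artificial_mask_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class _DirectionalEstimator(Module):
    """One recurrent direction: GRU state + linear read-out of the next week."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        self.gru = GRUCell(d + 2, hidden, rng)
        self.readout = Dense(hidden, d, rng)
        self.hidden = hidden
        self.d = d

    def run(self, x: np.ndarray, m: np.ndarray, dweek: np.ndarray) -> list[Tensor]:
        """Return per-step estimates X̂_t predicted from η_{t-1}.

        x: (N, T, d) standardized values (zeros at missing); m: (N, T)
        input mask; dweek: (T,) normalized gap to the previous assessment.
        """
        n, T, d = x.shape
        h = Tensor(np.zeros((n, self.hidden)))
        estimates = []
        for t in range(T):
            xhat = self.readout(h)
            estimates.append(xhat)
            mt = m[:, t : t + 1]
            xc = Tensor(x[:, t, :] * mt) + xhat * Tensor(1.0 - mt)
            extra = Tensor(
                np.column_stack([m[:, t], np.full(n, dweek[t])])
            )
            h = self.gru(concatenate([xc, extra], axis=-1), h)
        return estimates


class BritsImputer:
    """Bidirectional recurrent week-level imputer for gait cohorts."""

    def __init__(self, config: ImputerConfig | None = None):
        self.config = config or ImputerConfig()
        self._fitted = False

    # -- internals --------------------------------------------------------
    def _standardize(self, cohort: CohortTensor):
        obs = cohort.mask == 1
        rows = cohort.values[obs]
        self.mu_ = rows.mean(axis=0)
        self.sd_ = rows.std(axis=0)
        self.sd_[self.sd_ < 1e-8] = 1.0

    def _prep(self, cohort: CohortTensor) -> np.ndarray:
        z = (cohort.values - self.mu_) / self.sd_
        return z * cohort.mask[:, :, None]

    @staticmethod
    def _dweeks(weeks: tuple[int, ...]) -> np.ndarray:
        w = np.asarray(weeks, float)
        gaps = np.diff(w, prepend=w[0])
        return gaps / max(gaps.max(), 1.0)

    def _forward_backward(self, x, m, dweek):
        est_f = self.fwd_.run(x, m, dweek)
        est_b_rev = self.bwd_.run(x[:, ::-1, :], m[:, ::-1], dweek[::-1])
        est_b = est_b_rev[::-1]
        return est_f, est_b

    def _epoch_loss(self, x, m_input, m_score, dweek) -> Tensor:
        n, T, d = x.shape
        est_f, est_b = self._forward_backward(x, m_input, dweek)
        n_obs = max(m_score.sum() * d, 1.0)
        loss = Tensor(0.0)
        for t in range(T):
            target = Tensor(x[:, t, :])
            w = Tensor(m_score[:, t : t + 1])
            loss = loss + ((est_f[t] - target) ** 2 * w).sum()
            loss = loss + ((est_b[t] - target) ** 2 * w).sum()
        loss = loss * (1.0 / (2.0 * n_obs))
        miss = 1.0 - m_input
        n_miss = max(miss.sum() * d, 1.0)
        cons = Tensor(0.0)
        for t in range(T):
            w = Tensor(miss[:, t : t + 1])
            cons = cons + ((est_f[t] - est_b[t]) ** 2 * w).sum()
        return loss + cons * (self.config.consistency_weight / n_miss)

    # -- public API -------------------------------------------------------
    def fit(self, cohort: CohortTensor, hold_out_mask: np.ndarray | None = None
            ) -> "BritsImputer":
        """Train on a cohort.

        ``hold_out_mask`` (N, T) optionally marks observed entries to hide
        from the model entirely (used by the grid-search validation split).
        """
        cfg = self.config
        for i, pid in enumerate(cohort.patient_ids):
            if cohort.mask[i].sum() == 0:
                raise ValueError(f"patient {pid} has no observed weeks")
        rng = np.random.default_rng(cfg.seed)
        self._standardize(cohort)
        m = cohort.mask.astype(float)
        if hold_out_mask is not None:
            m = m * (1.0 - hold_out_mask)
        x = (cohort.values - self.mu_) / self.sd_
        x = x * m[:, :, None]
        dweek = self._dweeks(cohort.weeks)
        d = cohort.values.shape[2]
        self.fwd_ = _DirectionalEstimator(d, cfg.hidden_size, rng)
        self.bwd_ = _DirectionalEstimator(d, cfg.hidden_size, rng)
        params = self.fwd_.parameters() + self.bwd_.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        self.loss_history_: list[float] = []
        obs_idx = np.argwhere(m == 1)
        n_hide = max(1, int(round(cfg.artificial_mask_fraction * len(obs_idx))))
        for _ in range(cfg.epochs):
            hide = obs_idx[rng.choice(len(obs_idx), size=n_hide, replace=False)]
            m_in = m.copy()
            m_in[hide[:, 0], hide[:, 1]] = 0.0
            x_in = x * m_in[:, :, None]
            loss = self._epoch_loss(x_in, m_in, m, dweek)
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            # monitored loss: deterministic, full observed mask (no hiding)
            self.loss_history_.append(float(self._epoch_loss(x, m, m, dweek).data))
        self.weeks_ = tuple(cohort.weeks)
        self.d_ = d
        self._fitted = True
        return self

    def predict_estimates(self, cohort: CohortTensor) -> np.ndarray:
        """Mean of forward/backward week estimates, on the original scale."""
        if not self._fitted:
            raise RuntimeError("imputer is not trained")
        if cohort.values.shape[2] != self.d_ or tuple(cohort.weeks) != self.weeks_:
            raise ValueError("cohort layout does not match training layout")
        m = cohort.mask.astype(float)
        x = ((cohort.values - self.mu_) / self.sd_) * m[:, :, None]
        dweek = self._dweeks(cohort.weeks)
        est_f, est_b = self._forward_backward(x, m, dweek)
        est = np.stack(
            [(f.data + b.data) / 2.0 for f, b in zip(est_f, est_b)], axis=1
        )
        return est * self.sd_ + self.mu_

    def impute(self, cohort: CohortTensor) -> CohortTensor:
        """Fill missing weeks; observed weeks are returned bit-exactly."""
        est = self.predict_estimates(cohort)
        out = cohort.copy()
        filled = np.where(cohort.mask[:, :, None] == 1, cohort.values, est)
        out.values = filled
        out.week_provenance = np.where(cohort.mask == 1, "observed", "imputed")
        out.mask = np.ones_like(cohort.mask)
        return out


def impute_linear(cohort: CohortTensor) -> CohortTensor:
    """Per-patient linear interpolation across observed weeks (baseline).

    Interpolates each feature against the actual week value; weeks outside
    the observed range hold the nearest observed assessment.
    """
    out = cohort.copy()
    w = np.asarray(cohort.weeks, float)
    for i in range(cohort.n_patients):
        obs = cohort.mask[i] == 1
        if obs.sum() == 0:
            raise ValueError(f"patient {cohort.patient_ids[i]} has no observed weeks")
        miss = ~obs
        if miss.any():
            out.values[i, miss] = np.column_stack(
                [
                    np.interp(w[miss], w[obs], cohort.values[i, obs, j])
                    for j in range(cohort.values.shape[2])
                ]
            )
    out.week_provenance = np.where(cohort.mask == 1, "observed", "imputed")
    out.mask = np.ones_like(cohort.mask)
    return out


def grid_search_imputer(
    cohort: CohortTensor,
    grid: list[ImputerConfig],
    val_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[ImputerConfig, pd.DataFrame]:
    """Select the config minimizing MSE on a shared held-out validation mask.

    A fixed fraction of observed patient-weeks is hidden from every
    candidate during training and scored afterwards; ties break by grid
    order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(cohort.mask == 1)
    # keep each patient's first observed week as an anchor
    first_obs = {i: np.argmax(cohort.mask[i] == 1) for i in range(cohort.n_patients)}
    candidates = np.array(
        [k for k, (i, t) in enumerate(obs_idx) if t != first_obs[i]]
    )
    n_val = max(1, int(round(val_fraction * len(obs_idx))))
    n_val = min(n_val, len(candidates))
    chosen = obs_idx[rng.choice(candidates, size=n_val, replace=False)]
    hold = np.zeros_like(cohort.mask, dtype=float)
    hold[chosen[:, 0], chosen[:, 1]] = 1.0

    rows = []
    best = None
    for idx, cfg in enumerate(grid):
        if cfg.epochs > 0:
            imp = BritsImputer(cfg).fit(cohort, hold_out_mask=hold)
            est = imp.predict_estimates(cohort)
        else:  # degenerate config: untrained model, mean prediction
            imp = BritsImputer(replace(cfg, epochs=1)).fit(cohort, hold_out_mask=hold)
            est = np.broadcast_to(imp.mu_, cohort.values.shape)
        err = est[hold == 1] - cohort.values[hold == 1]
        mse = float((err**2).mean())
        rows.append({"config_index": idx, "val_mse": mse, **vars(cfg)})
        if best is None or mse < best[0]:
            best = (mse, cfg)
    return best[1], pd.DataFrame(rows)


__all__ = [
    "complement",
    "masked_reconstruction_loss",
    "ImputerConfig",
    "BritsImputer",
    "impute_linear",
    "grid_search_imputer",
]
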