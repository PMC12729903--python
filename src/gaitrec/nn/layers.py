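"""Neural layers built on the autodiff engine: dense, conv, GRU/LSTM cells."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, conv1d_same

__all__ = ["Dense", "Conv1d", "GRUCell", "LSTMCell", "BiLSTM", "Module"]


class Module:
    """Base class: parameter bookkeeping for optimizers and checkpoints."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded Conv1D along the time axis of (N, T, C_in) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.w = _glorot(rng, kernel * c_in, c_out, (kernel, c_in, c_out))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b)


class GRUCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.gates = Dense(d_in + d_hidden, 2 * d_hidden, rng)
        self.cand = Dense(d_in + d_hidden, d_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        zr = concatenate([x, h], axis=-1)
        g = self.gates(zr).sigmoid()
        z = g[:, : self.d_hidden]
        r = g[:, self.d_hidden :]
        h_tilde = self.cand(concatenate([x, r * h], axis=-1)).tanh()
        return z * h + (1.0 - z) * h_tilde


class LSTMCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.gates = Dense(d_in + d_hidden, 4 * d_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.d_hidden
        g = self.gates(concatenate([x, h], axis=-1))
        i = g[:, :H].sigmoid()
        f = g[:, H : 2 * H].sigmoid()
        o = g[:, 2 * H : 3 * H].sigmoid()
        u = g[:, 3 * H :].tanh()
        c_new = f * c + i * u
        return o * c_new.tanh(), c_new


class BiLSTM(Module):
    """Bidirectional LSTM over (N, T, C); returns (N, T, 2*hidden)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.fwd = LSTMCell(d_in, d_hidden, rng)
        self.bwd = LSTMCell(d_in, d_hidden, rng)

    def _run(self, cell: LSTMCell, steps: list[Tensor], n: int) -> list[Tensor]:
        h = Tensor(np.zeros((n, cell.d_hidden)))
        c = Tensor(np.zeros((n, cell.d_hidden)))
        outs = []
        for x in steps:
            h, c = cell(x, h, c)
            outs.append(h)
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        n, T, _ = x.shape
        steps = [x[:, t, :] for t in range(T)]
        f_out = self._run(self.fwd, steps, n)
        b_out = self._run(self.bwd, steps[::-1], n)[::-1]
        cols = [
            concatenate([f, b], axis=-1).reshape(n, 1, 2 * self.d_hidden)
            for f, b in zip(f_out, b_out)
        ]
        return concatenate(cols, axis=1)
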