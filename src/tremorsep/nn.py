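"""Convolutional (bi-directional) LSTM in plain numpy with manual backprop.

The classifier maps one 50-sample IMF window to a tremor probability:

    conv1d(30 filters, kernel 20, stride 1, relu) -> maxpool(2)
    -> conv1d(30 filters, kernel 10, stride 1, relu) -> maxpool(2)
    -> per-timestep dense(1 unit, relu)
    -> bi-directional LSTM (64 cells per direction)
    -> tanh on the final hidden states -> concat -> dense(1, sigmoid)

With 'same' convolution padding the sequence lengths run 50 -> 25 -> 25
-> 12, so the LSTM sees 12 timesteps of a 1-channel sequence; 'valid'
padding (50 -> 31 -> 15 -> 6 -> 3) is implemented too. The uni-directional
variant keeps only the forward LSTM.

Initialization follows the conventions deep-learning frameworks apply by
default: Glorot-uniform kernels, orthogonal recurrent matrices, zero biases
with the LSTM forget-gate bias at 1. Optimization is plain stochastic
gradient descent on binary cross-entropy. Everything is float64 and
seed-deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class BuildError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def _same_pads(kernel: int) -> tuple[int, int]:
    total = kernel - 1
    return total // 2, total - total // 2


def conv_output_len(t: int, kernel: int, padding: str) -> int:
    if padding == "same":
        return t
    out = t - kernel + 1
    if out < 1:
        raise BuildError(
            f"valid convolution collapses length {t} with kernel {kernel}")
    return out


def sequence_lengths(input_len: int, k1: int, k2: int, pool: int,
                     padding: str) -> list[int]:
    """Sequence length after each stage: conv1, pool1, conv2, pool2."""
    t1 = conv_output_len(input_len, k1, padding)
    t2 = t1 // pool
    t3 = conv_output_len(t2, k2, padding)
    t4 = t3 // pool
    if t4 < 1:
        raise BuildError(
            f"shape trace {input_len}->{t1}->{t2}->{t3}->{t4}: "
            "sequence collapsed to length 0")
    return [t1, t2, t3, t4]


class _Conv1D:
    def __init__(self, rng, kernel: int, c_in: int, c_out: int, padding: str):
        self.kernel, self.padding = kernel, padding
        self.W = _glorot_uniform(rng, (kernel, c_in, c_out),
                                 fan_in=kernel * c_in, fan_out=kernel * c_out)
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, C_in)
        if self.padding == "same":
            pl, pr = _same_pads(self.kernel)
            xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        else:
            xp = x
        win = sliding_window_view(xp, self.kernel, axis=1)  # (B, T_out, C, K)
        z = np.einsum("btck,kcf->btf", win, self.W, optimize=True) + self.b
        self._cache = (x.shape, xp, win, z)
        return np.maximum(z, 0.0)

    def backward(self, dout: np.ndarray):
        x_shape, xp, win, z = self._cache
        dz = dout * (z > 0)
        dW = np.einsum("btck,btf->kcf", win, dz, optimize=True)
        db = dz.sum(axis=(0, 1))
        contrib = np.einsum("btf,kcf->btkc", dz, self.W, optimize=True)
        dxp = np.zeros_like(xp)
        t_out = dz.shape[1]
        for k in range(self.kernel):
            dxp[:, k:k + t_out, :] += contrib[:, :, k, :]
        if self.padding == "same":
            pl, _ = _same_pads(self.kernel)
            dx = dxp[:, pl:pl + x_shape[1], :]
        else:
            dx = dxp
        return dx, {"W": dW, "b": db}


class _MaxPool1D:
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, c = x.shape
        t_out = t // self.size
        xt = x[:, : t_out * self.size, :].reshape(b, t_out, self.size, c)
        self._arg = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, t_out, c = dout.shape
        dxt = np.zeros((b, t_out, self.size, c))
        np.put_along_axis(dxt, self._arg[:, :, None, :],
                          dout[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, : t_out * self.size, :] = dxt.reshape(b, t_out * self.size, c)
        return dx


class _TimeDense:
    """Single dense unit applied per timestep (keeps the sequence axis)."""

    def __init__(self, rng, c_in: int, units: int = 1):
        self.W = _glorot_uniform(rng, (c_in, units), fan_in=c_in, fan_out=units)
        self.b = np.zeros(units)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W + self.b
        self._cache = (x, z)
        return np.maximum(z, 0.0)

    def backward(self, dout: np.ndarray):
        x, z = self._cache
        dz = dout * (z > 0)
        dW = np.einsum("bti,btj->ij", x, dz)
        db = dz.sum(axis=(0, 1))
        dx = dz @ self.W.T
        return dx, {"W": dW, "b": db}


class _LSTM:
    """Single-direction LSTM returning the final hidden state.

    Gate order i, f, g, o; forget bias initialized to 1.
    """

    def __init__(self, rng, c_in: int, hidden: int):
        self.h = hidden
        self.Wx = _glorot_uniform(rng, (c_in, 4 * hidden),
                                  fan_in=c_in, fan_out=4 * hidden)
        self.Wh = np.hstack([_orthogonal(rng, hidden, hidden)
                             for _ in range(4)])
        self.b = np.zeros(4 * hidden)
        self.b[hidden: 2 * hidden] = 1.0  # unit forget bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        hdim = self.h
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim: 2 * hdim])
            g = np.tanh(z[:, 2 * hdim: 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        self._cache = (cache, x.shape)
        return h

    def backward(self, dh_final: np.ndarray):
        cache, x_shape = self._cache
        hdim = self.h
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros(x_shape)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for step in range(len(cache) - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new = cache[step]
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.hstack([di * i * (1 - i), df * f * (1 - f),
                            dg * (1 - g ** 2), do * o * (1 - o)])
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class ConvRecurrentNet:
    """The full classifier; ``bidirectional=False`` gives the conv-LSTM
    baseline (same convolutional front-end, one LSTM direction)."""

    def __init__(self, input_len: int = 50, conv1_filters: int = 30,
                 conv1_kernel: int = 20, conv2_filters: int = 30,
                 conv2_kernel: int = 10, pool: int = 2, fc_units: int = 1,
                 lstm_cells: int = 64, bidirectional: bool = True,
                 padding: str = "same", post_lstm_tanh: bool = True,
                 seed: int = 0):
        if padding not in ("same", "valid"):
            raise BuildError(f"unknown padding mode {padding!r}")
        self.input_len = input_len
        self.bidirectional = bidirectional
        self.post_lstm_tanh = post_lstm_tanh
        self.seq_lens = sequence_lengths(input_len, conv1_kernel,
                                         conv2_kernel, pool, padding)
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv1D(rng, conv1_kernel, 1, conv1_filters, padding)
        self.pool1 = _MaxPool1D(pool)
        self.conv2 = _Conv1D(rng, conv2_kernel, conv1_filters, conv2_filters,
                             padding)
        self.pool2 = _MaxPool1D(pool)
        self.fc = _TimeDense(rng, conv2_filters, fc_units)
        self.lstm_f = _LSTM(rng, fc_units, lstm_cells)
        self.lstm_b = _LSTM(rng, fc_units, lstm_cells) if bidirectional else None
        merged = lstm_cells * (2 if bidirectional else 1)
        self.Wout = _glorot_uniform(rng, (merged, 1), fan_in=merged, fan_out=1)
        self.bout = np.zeros(1)

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {
            "conv1.W": self.conv1.W, "conv1.b": self.conv1.b,
            "conv2.W": self.conv2.W, "conv2.b": self.conv2.b,
            "fc.W": self.fc.W, "fc.b": self.fc.b,
            "lstm_f.Wx": self.lstm_f.Wx, "lstm_f.Wh": self.lstm_f.Wh,
            "lstm_f.b": self.lstm_f.b,
            "out.W": self.Wout, "out.b": self.bout,
        }
        if self.bidirectional:
            params.update({"lstm_b.Wx": self.lstm_b.Wx,
                           "lstm_b.Wh": self.lstm_b.Wh,
                           "lstm_b.b": self.lstm_b.b})
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    # -- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (B, input_len) -> probabilities (B,)."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_len:
            raise ValueError(
                f"expected windows of length {self.input_len}, got {X.shape[1]}")
        h = X[:, :, None]
        h = self.pool1.forward(self.conv1.forward(h))
        h = self.pool2.forward(self.conv2.forward(h))
        seq = self.fc.forward(h)                       # (B, T, 1)
        hf = self.lstm_f.forward(seq)
        if self.bidirectional:
            hb = self.lstm_b.forward(seq[:, ::-1, :])
            merged = np.concatenate([hf, hb], axis=1)
        else:
            merged = hf
        if self.post_lstm_tanh:
            self._pre_tanh = merged
            merged = np.tanh(merged)
        self._merged = merged
        logits = merged @ self.Wout + self.bout
        self._probs = _sigmoid(logits[:, 0])
        return self._probs

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy wrt all parameters.

        Must follow a forward() call on the same batch.
        """
        p = self._probs
        b = p.size
        dlogit = ((p - y) / b)[:, None]               # sigmoid+BCE combined
        grads = {"out.W": self._merged.T @ dlogit,
                 "out.b": dlogit.sum(axis=0)}
        dmerged = dlogit @ self.Wout.T
        if self.post_lstm_tanh:
            dmerged = dmerged * (1.0 - np.tanh(self._pre_tanh) ** 2)
        if self.bidirectional:
            hcells = self.lstm_f.h
            dseq_f, gf = self.lstm_f.backward(dmerged[:, :hcells])
            dseq_b, gb = self.lstm_b.backward(dmerged[:, hcells:])
            dseq = dseq_f + dseq_b[:, ::-1, :]
            grads.update({f"lstm_f.{k}": v for k, v in gf.items()})
            grads.update({f"lstm_b.{k}": v for k, v in gb.items()})
        else:
            dseq, gf = self.lstm_f.backward(dmerged)
            grads.update({f"lstm_f.{k}": v for k, v in gf.items()})
        dh, gfc = self.fc.backward(dseq)
        grads.update({f"fc.{k}": v for k, v in gfc.items()})
        dh = self.pool2.backward(dh)
        dh, g2 = self.conv2.backward(dh)
        grads.update({f"conv2.{k}": v for k, v in g2.items()})
        dh = self.pool1.backward(dh)
        _, g1 = self.conv1.backward(dh)
        grads.update({f"conv1.{k}": v for k, v in g1.items()})
        return grads

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self.forward(X), 1e-12, 1 - 1e-12)
        y = np.asarray(y, float)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def sgd_step(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One mini-batch SGD update; returns the batch loss."""
        p = np.clip(self.forward(X), 1e-12, 1 - 1e-12)
        y = np.asarray(y, float)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        grads = self.backward(y)
        params = self.parameters()
        for name, g in grads.items():
            params[name] -= lr * g.reshape(params[name].shape)
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = [self.forward(X[i: i + batch_size])
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out)
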