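"""Layers: LSTM, Dropout, Dense and the softmax activation.

Conventions
-----------
* Sequence tensors are ``(batch, time, features)``; flat tensors are
  ``(batch, features)``.
* Each layer exposes ``forward(x, train, rng)`` and ``backward(dout)``;
  ``backward`` accumulates parameter gradients in ``self.grads`` and
  returns the gradient with respect to the layer input.
* Parameters live in ``self.params`` keyed by name, so optimisers can
  iterate layers generically.
* All arithmetic is float32 for speed; gradients are exact within that
  precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

try:  # optional JIT of the recurrence loops
    from ._kernels import lstm_backward_loop, lstm_forward_loop

    _HAVE_KERNELS = True
except ImportError:  # pragma: no cover - numba always present in practice
    _HAVE_KERNELS = False

__all__ = ["softmax", "sigmoid", "Layer", "LSTM", "Dropout", "Dense"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction for overflow safety.

    Mathematically identical to ``exp(y_i) / sum_k exp(y_k)``; subtracting
    the row maximum leaves the value unchanged (shift invariance) while
    keeping every exponent <= 0.
    """
    shifted = logits - np.max(logits, axis=axis, keepdims=True)
    ex = np.exp(shifted)
    return ex / np.sum(ex, axis=axis, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer; stateless layers leave ``params``/``grads`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError


class LSTM(Layer):
    """Standard (no-peephole) LSTM over a batch of sequences.

    Per timestep, with the previous hidden state ``h`` and cell state
    ``c`` (both zero-initialised):

    .. code-block:: text

        f_t = sigmoid(x_t Wx_f + h_{t-1} Wh_f + b_f)     forget gate
        i_t = sigmoid(x_t Wx_i + h_{t-1} Wh_i + b_i)     input gate
        o_t = sigmoid(x_t Wx_o + h_{t-1} Wh_o + b_o)     output gate
        g_t = tanh   (x_t Wx_g + h_{t-1} Wh_g + b_g)     candidate cell
        c_t = f_t * c_{t-1} + i_t * g_t
        h_t = o_t * tanh(c_t)

    ``return_sequences=True`` yields ``(B, T, units)``; otherwise only the
    final hidden state ``(B, units)``.  The forget-gate bias is
    initialised to 1 (long-memory default); input and recurrent weights
    are Glorot-uniform from the run seed.
    """

    def __init__(
        self,
        input_dim: int,
        units: int,
        *,
        return_sequences: bool = False,
        input_init: str = "glorot",
        rng: np.random.Generator,
    ):
        super().__init__()
        self.input_dim = input_dim
        self.units = units
        self.return_sequences = return_sequences
        H = units
        # gate order along the last axis: [i, f, o, g]
        if input_init == "fan_in":
            # LeCun-style uniform(+-sqrt(3/fan_in)); for scalar-per-step
            # input (fan_in 1) this keeps the gate drive at input scale,
            # where Glorot's fan-out-dominated limit (~0.15) would leave
            # the cell's input response quadratically small
            limit = np.sqrt(3.0 / input_dim)
            Wx = rng.uniform(-limit, limit, (input_dim, 4 * H)).astype(np.float32)
        elif input_init == "glorot":
            Wx = glorot_uniform(rng, (input_dim, 4 * H))
        else:
            raise ValueError(f"unknown input_init {input_init!r}")
        self.params = {
            "Wx": Wx,
            "Wh": glorot_uniform(rng, (H, 4 * H)),
            "b": np.zeros(4 * H, dtype=np.float32),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias
        self._cache = None

    def forward(self, x: np.ndarray, *, train=False, rng=None) -> np.ndarray:
        # time-major (T, B, .) internally: every per-step slice contiguous
        x = np.ascontiguousarray(x, dtype=np.float32)
        B, T, D = x.shape
        H = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        x_t = np.ascontiguousarray(x.transpose(1, 0, 2))
        # input contribution for every timestep in one matmul
        a_x = (x_t.reshape(T * B, D) @ Wx).reshape(T, B, 4 * H) + b
        a_x = np.ascontiguousarray(a_x)
        bufs = [np.empty((T, B, H), np.float32) for _ in range(7)]
        i, f, o, g, c, tanh_c, h = bufs
        if _HAVE_KERNELS:
            lstm_forward_loop(a_x, Wh, i, f, o, g, c, tanh_c, h)
        else:
            h_t = np.zeros((B, H), np.float32)
            c_t = np.zeros((B, H), np.float32)
            for t in range(T):
                a = a_x[t] + h_t @ Wh
                gates = sigmoid(a[:, : 3 * H])
                i[t] = gates[:, :H]
                f[t] = gates[:, H : 2 * H]
                o[t] = gates[:, 2 * H :]
                g[t] = np.tanh(a[:, 3 * H :])
                c_t = f[t] * c_t + i[t] * g[t]
                c[t] = c_t
                tanh_c[t] = np.tanh(c_t)
                h_t = o[t] * tanh_c[t]
                h[t] = h_t
        self._cache = (x_t, i, f, o, g, c, tanh_c, h)
        if self.return_sequences:
            return np.ascontiguousarray(h.transpose(1, 0, 2))
        return h[-1].copy()

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_t, i, f, o, g, c, tanh_c, h = self._cache
        T, B, D = x_t.shape
        H = self.units
        Wh = self.params["Wh"]
        if self.return_sequences:
            dh_out = np.ascontiguousarray(
                np.asarray(dout, dtype=np.float32).transpose(1, 0, 2)
            )
        else:
            dh_out = np.zeros((T, B, H), np.float32)
            dh_out[-1] = dout
        da_all = np.empty((T, B, 4 * H), np.float32)
        WhT = np.ascontiguousarray(Wh.T)
        if _HAVE_KERNELS:
            lstm_backward_loop(dh_out, WhT, i, f, o, g, c, tanh_c, da_all)
        else:
            dh_next = np.zeros((B, H), np.float32)
            dc_next = np.zeros((B, H), np.float32)
            for t in range(T - 1, -1, -1):
                dh = dh_out[t] + dh_next
                c_prev = c[t - 1] if t > 0 else np.zeros((B, H), np.float32)
                do = dh * tanh_c[t]
                dc = dc_next + dh * o[t] * (1.0 - tanh_c[t] ** 2)
                dc_next = dc * f[t]
                da = da_all[t]
                da[:, :H] = dc * g[t] * i[t] * (1.0 - i[t])
                da[:, H : 2 * H] = dc * c_prev * f[t] * (1.0 - f[t])
                da[:, 2 * H : 3 * H] = do * o[t] * (1.0 - o[t])
                da[:, 3 * H :] = dc * i[t] * (1.0 - g[t] ** 2)
                dh_next = da @ WhT
        # weight gradients accumulate over all steps in three matmuls
        da_flat = da_all.reshape(T * B, 4 * H)
        self.grads["Wx"] = x_t.reshape(T * B, D).T @ da_flat
        h_prev = np.concatenate([np.zeros((1, B, H), np.float32), h[:-1]])
        self.grads["Wh"] = h_prev.reshape(T * B, H).T @ da_flat
        self.grads["b"] = da_flat.sum(axis=0)
        dx_t = (da_flat @ self.params["Wx"].T).reshape(T, B, D)
        return np.ascontiguousarray(dx_t.transpose(1, 0, 2))


class Dropout(Layer):
    """Inverted dropout: during training each unit is zeroed independently
    with probability ``rate`` and survivors are scaled by ``1/(1-rate)``,
    so inference is the identity map."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Affine map ``x W + b`` on flat ``(B, features)`` input, optionally
    followed by a ReLU."""

    def __init__(
        self,
        input_dim: int,
        units: int,
        *,
        relu: bool = False,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.relu = relu
        self.params = {
            "W": glorot_uniform(rng, (input_dim, units)),
            "b": np.zeros(units, dtype=np.float32),
        }
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            out = np.maximum(z, 0.0)
            self._cache = (x, z)
            return out
        self._cache = (x, None)
        return z

    def backward(self, dout):
        x, z = self._cache
        if self.relu:
            dout = dout * (z > 0)
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T
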