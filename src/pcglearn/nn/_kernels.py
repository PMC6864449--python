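"""Numba-JIT kernels for the LSTM recurrence.

The per-timestep loop dominates training cost; these kernels fuse the
gate nonlinearities and elementwise updates so only the two matmuls per
step hit BLAS.  All sequence arrays are time-major ``(T, B, units)`` so
every per-step slice is contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lstm_forward_loop", "lstm_backward_loop"]

#: Backward-pass gradients below this magnitude are flushed to zero.  BPTT
#: gradients decay geometrically and reach the float32 subnormal range
#: (~1e-38) within a few hundred timesteps; subnormal arithmetic is
#: handled by microcode on x86 and runs orders of magnitude slower, so
#: flushing is both a large speedup and numerically inconsequential.
_FLUSH = np.float32(1e-30)


@njit(cache=True)
def lstm_forward_loop(a_x, Wh, i, f, o, g, c, tanh_c, h):
    """In-place forward recurrence.

    a_x : (T, B, 4H) input projections + bias, pre-computed
    Wh  : (H, 4H) recurrent weights
    i, f, o, g, c, tanh_c, h : (T, B, H) output buffers
    """
    T, B, H4 = a_x.shape
    H = H4 // 4
    h_t = np.zeros((B, H), np.float32)
    c_t = np.zeros((B, H), np.float32)
    for t in range(T):
        a = a_x[t] + np.dot(h_t, Wh)
        for b_i in range(B):
            for k in range(H):
                i_v = 1.0 / (1.0 + np.exp(-a[b_i, k]))
                f_v = 1.0 / (1.0 + np.exp(-a[b_i, H + k]))
                o_v = 1.0 / (1.0 + np.exp(-a[b_i, 2 * H + k]))
                g_v = np.tanh(a[b_i, 3 * H + k])
                c_v = f_v * c_t[b_i, k] + i_v * g_v
                tc = np.tanh(c_v)
                h_v = o_v * tc
                i[t, b_i, k] = i_v
                f[t, b_i, k] = f_v
                o[t, b_i, k] = o_v
                g[t, b_i, k] = g_v
                c[t, b_i, k] = c_v
                tanh_c[t, b_i, k] = tc
                h[t, b_i, k] = h_v
                c_t[b_i, k] = c_v
        h_t = h[t]


@njit(cache=True)
def lstm_backward_loop(dh_out, WhT, i, f, o, g, c, tanh_c, da_all):
    """In-place backward recurrence; fills da_all (T, B, 4H) with the
    gradients at the pre-nonlinearity gate activations."""
    T, B, H = i.shape
    dh_next = np.zeros((B, H), np.float32)
    dc_next = np.zeros((B, H), np.float32)
    for t in range(T - 1, -1, -1):
        for b_i in range(B):
            for k in range(H):
                dh = dh_out[t, b_i, k] + dh_next[b_i, k]
                if -_FLUSH < dh < _FLUSH:
                    dh = np.float32(0.0)
                if -_FLUSH < dc_next[b_i, k] < _FLUSH:
                    dc_next[b_i, k] = np.float32(0.0)
                i_v = i[t, b_i, k]
                f_v = f[t, b_i, k]
                o_v = o[t, b_i, k]
                g_v = g[t, b_i, k]
                tc = tanh_c[t, b_i, k]
                c_prev = c[t - 1, b_i, k] if t > 0 else np.float32(0.0)
                do = dh * tc
                dc = dc_next[b_i, k] + dh * o_v * (1.0 - tc * tc)
                di = dc * g_v
                df = dc * c_prev
                dg = dc * i_v
                dc_next[b_i, k] = dc * f_v
                da_all[t, b_i, k] = di * i_v * (1.0 - i_v)
                da_all[t, b_i, H + k] = df * f_v * (1.0 - f_v)
                da_all[t, b_i, 2 * H + k] = do * o_v * (1.0 - o_v)
                da_all[t, b_i, 3 * H + k] = dg * (1.0 - g_v * g_v)
        dh_next = np.dot(da_all[t], WhT)
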