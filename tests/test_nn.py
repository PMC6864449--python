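"""Neural-network substrate: LSTM cell semantics, dropout, softmax,
gradient correctness."""

import numpy as np
import pytest
from scipy.stats import binomtest

from pcglearn.nn import LSTM, Dense, Dropout, SequentialNet, cross_entropy, softmax


def lstm_scalar_oracle(x, Wx, Wh, b, return_sequences=False):
    """Independent scalar-loop LSTM reference (float64, no vectorisation).

    Gate order along the packed axis is [input, forget, output, candidate];
    the recurrence starts from h0 = c0 = 0:

        f_t = sigmoid(x_t Wx_f + h_{t-1} Wh_f + b_f)
        i_t = sigmoid(x_t Wx_i + h_{t-1} Wh_i + b_i)
        o_t = sigmoid(x_t Wx_o + h_{t-1} Wh_o + b_o)
        c_t = f_t c_{t-1} + i_t tanh(x_t Wx_c + h_{t-1} Wh_c + b_c)
        h_t = o_t tanh(c_t)
    """
    T, D = x.shape
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    seq = []
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for t in range(T):
        a = np.zeros(4 * H)
        for j in range(4 * H):
            s = b[j]
            for d in range(D):
                s += x[t, d] * Wx[d, j]
            for k in range(H):
                s += h[k] * Wh[k, j]
            a[j] = s
        i_g = sig(a[:H])
        f_g = sig(a[H : 2 * H])
        o_g = sig(a[2 * H : 3 * H])
        g_g = np.tanh(a[3 * H :])
        c = f_g * c + i_g * g_g
        h = o_g * np.tanh(c)
        seq.append(h.copy())
    return np.array(seq) if return_sequences else h


class TestLSTMCell:
    @pytest.mark.parametrize("T,H,D", [(1, 1, 1), (3, 2, 1), (5, 4, 2)])
    def test_matches_scalar_loop_oracle(self, T, H, D, rng):
        cell = LSTM(D, H, return_sequences=True, rng=np.random.default_rng(0))
        # small, well-conditioned weights
        for k in cell.params:
            cell.params[k] = (
                0.5 * rng.standard_normal(cell.params[k].shape)
            ).astype(np.float32)
        x = rng.standard_normal((1, T, D)).astype(np.float32)
        out = cell.forward(x)[0]
        ref = lstm_scalar_oracle(
            x[0].astype(np.float64),
            cell.params["Wx"].astype(np.float64),
            cell.params["Wh"].astype(np.float64),
            cell.params["b"].astype(np.float64),
            return_sequences=True,
        )
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_zero_weights_give_zero_state(self):
        """All weights and biases zero: every gate = 0.5, the candidate is
        tanh(0) = 0, so c_t = h_t = 0 for every t."""
        cell = LSTM(1, 4, return_sequences=True, rng=np.random.default_rng(0))
        for k in cell.params:
            cell.params[k] = np.zeros_like(cell.params[k])
        out = cell.forward(np.ones((2, 6, 1), np.float32))
        np.testing.assert_array_equal(out, np.zeros((2, 6, 4)))

    def test_single_timestep_hand_computed(self):
        """Scalar cell (H=D=1) with hand-set weights, one timestep."""
        cell = LSTM(1, 1, rng=np.random.default_rng(0))
        # order [i, f, o, g]
        cell.params["Wx"] = np.array([[0.1, 0.2, 0.3, 0.4]], np.float32)
        cell.params["Wh"] = np.zeros((1, 4), np.float32)
        cell.params["b"] = np.array([0.01, 0.02, 0.03, 0.04], np.float32)
        x = np.array([[[2.0]]], np.float32)
        h = float(cell.forward(x)[0, 0])
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        i_g = sig(0.1 * 2 + 0.01)
        o_g = sig(0.3 * 2 + 0.03)
        g_g = np.tanh(0.4 * 2 + 0.04)
        c = i_g * g_g  # c0 = 0 so the forget term vanishes
        expected = o_g * np.tanh(c)
        assert h == pytest.approx(expected, abs=1e-6)

    def test_gate_values_bounded(self, rng):
        cell = LSTM(1, 3, return_sequences=True, rng=np.random.default_rng(1))
        x = rng.standard_normal((2, 50, 1)).astype(np.float32)
        out = cell.forward(x)
        _, i, f, o, g, c, tanh_c, h = cell._cache
        for gate in (i, f, o):
            assert np.all(gate > 0) and np.all(gate < 1)
        assert np.all(np.isfinite(c)) and np.all(np.isfinite(h))


class TestSoftmax:
    def test_uniform_on_equal_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.full(3, 1 / 3))

    def test_large_logits_no_overflow(self):
        out = softmax(np.array([1000.0, 0.0, 0.0]))
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    def test_direct_evaluation(self):
        np.testing.assert_allclose(
            softmax(np.array([1.0, 2.0, 3.0])),
            [0.09003, 0.24473, 0.66524],
            atol=5e-6,
        )

    def test_rows_sum_to_one_and_shift_invariant(self, rng):
        logits = rng.standard_normal((20, 3)) * 10
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(p, softmax(logits + 123.4), atol=1e-9)


class TestDropout:
    def test_training_drop_fraction_binomial(self):
        """Expected dropped fraction equals the rate (binomial test over
        10,000 draws at alpha = 0.01)."""
        rate = 0.35
        layer = Dropout(rate)
        rng = np.random.default_rng(3)
        x = np.ones((100, 100), np.float32)
        out = layer.forward(x, train=True, rng=rng)
        dropped = int(np.sum(out == 0))
        assert binomtest(dropped, 10_000, rate).pvalue > 0.01

    def test_survivors_scaled_inverted(self):
        layer = Dropout(0.5)
        out = layer.forward(
            np.ones((50, 50), np.float32), train=True,
            rng=np.random.default_rng(0),
        )
        kept = out[out != 0]
        np.testing.assert_allclose(kept, 2.0)

    def test_inference_is_identity(self, rng):
        layer = Dropout(0.35)
        x = rng.standard_normal((10, 10)).astype(np.float32)
        np.testing.assert_array_equal(layer.forward(x, train=False), x)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            Dropout(1.0)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central finite differences
        on every parameter with non-negligible gradient."""
        rng = np.random.default_rng(0)
        net = SequentialNet(
            [
                LSTM(2, 4, return_sequences=True, rng=rng),
                LSTM(4, 3, rng=rng),
                Dense(3, 3, rng=rng),
            ]
        )
        B, T, D = 4, 5, 2
        x = rng.standard_normal((B, T, D)).astype(np.float32)
        y = rng.integers(0, 3, B)

        def loss():
            return cross_entropy(softmax(net.logits(x)), y)

        probs = softmax(net.logits(x, train=True))
        onehot = np.zeros((B, 3), np.float32)
        onehot[np.arange(B), y] = 1.0
        d = (probs.astype(np.float32) - onehot) / B
        for layer in reversed(net.layers):
            d = layer.backward(d)

        eps = 1e-2
        checked = 0
        for layer in net.layers:
            for k, w in layer.params.items():
                g = layer.grads[k]
                flat = np.argsort(np.abs(g).ravel())[-5:]  # largest grads
                for fi in flat:
                    idx = np.unravel_index(fi, w.shape)
                    if abs(g[idx]) < 1e-3:
                        continue
                    orig = w[idx]
                    w[idx] = orig + eps
                    lp = loss()
                    w[idx] = orig - eps
                    lm = loss()
                    w[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    assert num == pytest.approx(float(g[idx]), rel=0.05, abs=1e-4)
                    checked += 1
        assert checked >= 10
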