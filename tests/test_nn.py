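"""Engine-level checks: exact gradients, dropout semantics, determinism."""

import numpy as np
import pytest

from vowelbci import _nn


def _to_float64(layers):
    for l in layers:
        if isinstance(l, (_nn.Conv2D, _nn.Dense)):
            l.W = l.W.astype(np.float64)
            l.b = l.b.astype(np.float64)
            l.params = [l.W, l.b]
            l.grads = [np.zeros_like(l.W), np.zeros_like(l.b)]
        if isinstance(l, _nn.BatchNorm):
            l.gamma = l.gamma.astype(np.float64)
            l.beta = l.beta.astype(np.float64)
            l.params = [l.gamma, l.beta]
            l.grads = [np.zeros_like(l.gamma), np.zeros_like(l.beta)]
    return layers


def _fd_check(layers, input_shape, seed=0, tol=1e-6, stride=8):
    rng = np.random.default_rng(seed)
    net = _nn.Network(_to_float64(layers))
    X = rng.normal(size=(4, *input_shape))
    t = np.array([0, 1, 0, 1])

    def loss_fn():
        return _nn.softmax_cross_entropy(net.forward(X, train=True), t)

    _, grad = loss_fn()
    net.backward(grad)
    for l in net.layers:
        for p, g in zip(l.params, l.grads):
            analytic = g.copy()
            flat = list(np.ndindex(p.shape))
            for ix in flat[:: max(1, len(flat) // stride)]:
                eps, old = 1e-6, p[ix]
                p[ix] = old + eps
                l1, _ = loss_fn()
                p[ix] = old - eps
                l2, _ = loss_fn()
                p[ix] = old
                num = (l1 - l2) / (2 * eps)
                if abs(num) < 1e-9 and abs(analytic[ix]) < 1e-9:
                    continue
                rel = abs(num - analytic[ix]) / max(abs(num), abs(analytic[ix]), 1e-7)
                assert rel < tol, f"{type(l).__name__} grad mismatch: {rel:.2e}"


class TestGradients:
    def test_conv_matches_naive_convolution(self):
        rng = np.random.default_rng(1)
        B, H, W, C, F, kh, kw = 3, 6, 5, 2, 4, 3, 2
        conv = _nn.Conv2D(C, F, (kh, kw), rng)
        conv.W = conv.W.astype(np.float64)
        conv.b = rng.normal(size=F)
        conv.params = [conv.W, conv.b]
        conv.grads = [np.zeros_like(conv.W), np.zeros_like(conv.b)]
        x = rng.normal(size=(B, H, W, C))
        out = conv.forward(x, True)
        OH, OW = H - kh + 1, W - kw + 1
        Wk = conv.W.reshape(kh, kw, C, F)
        ref = np.zeros((B, OH, OW, F))
        for i in range(OH):
            for j in range(OW):
                patch = x[:, i : i + kh, j : j + kw, :]
                ref[:, i, j, :] = np.tensordot(patch, Wk, axes=3) + conv.b
        np.testing.assert_allclose(out, ref, atol=1e-10)

        dout = rng.normal(size=out.shape)
        dx = conv.backward(dout)
        dWr = np.zeros_like(Wk)
        dxr = np.zeros_like(x)
        for i in range(OH):
            for j in range(OW):
                patch = x[:, i : i + kh, j : j + kw, :]
                dWr += np.tensordot(patch, dout[:, i, j, :], axes=([0], [0]))
                dxr[:, i : i + kh, j : j + kw, :] += np.tensordot(dout[:, i, j, :], Wk, axes=([1], [3]))
        np.testing.assert_allclose(conv.grads[0], dWr.reshape(-1, F), atol=1e-10)
        np.testing.assert_allclose(conv.grads[1], dout.sum(axis=(0, 1, 2)), atol=1e-10)
        np.testing.assert_allclose(dx, dxr, atol=1e-10)

    def test_conv_bn_relu_dense_stack(self):
        rng = np.random.default_rng(0)
        layers = [
            _nn.Conv2D(2, 3, (3, 3), rng),
            _nn.BatchNorm(3),
            _nn.ReLU(),
            _nn.Flatten(),
            _nn.Dense(3 * 7 * 5, 2, rng),
        ]
        _fd_check(layers, (9, 7, 2))

    def test_pool_and_double_bn_stack(self):
        rng = np.random.default_rng(2)
        layers = [
            _nn.Conv2D(1, 3, (3, 3), rng),
            _nn.BatchNorm(3),
            _nn.MaxPool2D((2, 2)),
            _nn.BatchNorm(3),
            _nn.Flatten(),
            _nn.Dense(3 * 3 * 2, 2, rng),
        ]
        # looser tolerance: perturbing BN parameters can flip a max-pool
        # argmax, a genuine nonsmoothness of the loss surface
        _fd_check(layers, (9, 7, 1), tol=1e-4)


class TestDropout:
    def test_exact_count_masks_exact_fraction(self):
        rng = np.random.default_rng(0)
        d = _nn.Dropout(0.25, rng, mode="exact")
        x = np.ones((10, 32, 91, 1), dtype=np.float32)
        out = d.forward(x, train=True)
        n = 32 * 91
        expected_zeros = int(0.25 * n)
        for i in range(10):
            assert (out[i] == 0).sum() == expected_zeros

    def test_bernoulli_fraction_within_mc_tolerance(self):
        rng = np.random.default_rng(0)
        d = _nn.Dropout(0.25, rng, mode="bernoulli")
        x = np.ones((20, 32, 91, 1), dtype=np.float32)
        out = d.forward(x, train=True)
        frac = (out == 0).mean()
        n = out.size
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_inactive_at_inference(self):
        rng = np.random.default_rng(0)
        d = _nn.Dropout(0.25, rng)
        x = np.ones((2, 4, 4, 1))
        np.testing.assert_array_equal(d.forward(x, train=False), x)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            _nn.Dropout(1.0, np.random.default_rng(0))


class TestOptimizer:
    def test_momentum_update_rule(self):
        rng = np.random.default_rng(0)
        dense = _nn.Dense(2, 2, rng)
        dense.W = np.zeros((2, 2))
        dense.params = [dense.W, dense.b]
        dense.grads = [np.ones((2, 2)), np.zeros(2)]
        net = _nn.Network([dense])
        opt = _nn.SGDMomentum(net, learning_rate=0.1, momentum=0.9)
        opt.step()  # v = -0.1*g; p = -0.1
        np.testing.assert_allclose(dense.W, -0.1)
        opt.step()  # v = 0.9*(-0.1) - 0.1 = -0.19; p = -0.29
        np.testing.assert_allclose(dense.W, -0.29)


class TestBatchNormFinalization:
    def test_population_stats_collected(self):
        bn = _nn.BatchNorm(2)
        rng = np.random.default_rng(0)
        x = rng.normal(loc=3.0, scale=2.0, size=(50, 4, 4, 2))
        bn.start_collect()
        for s in range(0, 50, 10):
            bn.forward(x[s : s + 10], train=False)
        bn.finish_collect()
        np.testing.assert_allclose(bn.running_mean, x.mean(axis=(0, 1, 2)), atol=1e-6)
        np.testing.assert_allclose(bn.running_var, x.var(axis=(0, 1, 2)), rtol=0.05)
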