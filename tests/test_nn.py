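"""The numpy network engine: analytic gradients vs finite differences,
layer mechanics, optimizer behavior."""

import numpy as np
import pytest

from pafnet import nn


def numeric_vs_analytic(layers, x, y, rng, n_per_param=8):
    """Max absolute gradient discrepancy over sampled parameter entries."""
    net = nn.Sequential(layers)
    for l in layers:  # freeze running-stat side effects during the check
        if isinstance(l, nn.BatchNorm):
            l.momentum = 1.0

    def loss():
        return nn.bce_loss(net.forward(x, training=True), y)

    p0 = net.forward(x, training=True)
    net.backward(nn.bce_grad(p0, y))
    worst = 0.0
    for p in [q for q in net.params() if q.trainable]:
        flat, g = p.value.ravel(), p.grad.ravel()
        for idx in rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False):
            h = 1e-6
            old = flat[idx]
            flat[idx] = old + h
            lp = loss()
            flat[idx] = old - h
            lm = loss()
            flat[idx] = old
            num = (lp - lm) / (2 * h)
            # mixed tolerance: near-zero gradients (e.g. conv bias ahead of a
            # batchnorm) sit at the finite-difference noise floor
            worst = max(worst, abs(num - g[idx]) - 1e-4 * (abs(num) + abs(g[idx])))
    return worst


class TestGradients:
    def test_full_stack_matches_finite_differences(self, rng):
        F = np.float64
        layers = [
            nn.Conv1D(1, 3, 1, rng, dtype=F), nn.BatchNorm(3, dtype=F), nn.ReLU(),
            nn.Conv1D(3, 4, 8, rng, dtype=F), nn.BatchNorm(4, dtype=F), nn.ReLU(),
            nn.MaxPool1D(2),
            nn.Conv1D(4, 5, 8, rng, dtype=F), nn.BatchNorm(5, dtype=F), nn.ReLU(),
            nn.MaxPool1D(2),
            nn.Flatten(),
            nn.Dense(5 * 5, 6, rng, dtype=F), nn.BatchNorm(6, dtype=F), nn.ReLU(),
            nn.Dense(6, 1, rng, dtype=F), nn.Sigmoid(),
        ]
        x = rng.standard_normal((8, 1, 17))  # odd length exercises ceil pooling
        y = rng.integers(0, 2, size=(8, 1)).astype(float)
        assert numeric_vs_analytic(layers, x, y, rng) < 1e-6

    def test_input_gradient_through_batchnorm(self, rng):
        bn = nn.BatchNorm(3, dtype=np.float64)
        bn.momentum = 1.0
        x = rng.standard_normal((4, 3, 5))
        w = rng.standard_normal((4, 3, 5))
        bn.forward(x, training=True)
        gx = bn.backward(w.copy())
        num = np.zeros_like(x)
        h = 1e-6
        for i in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (np.sum(bn.forward(xp, training=True) * w)
                      - np.sum(bn.forward(xm, training=True) * w)) / (2 * h)
        np.testing.assert_allclose(gx, num, atol=1e-7)


class TestLayerMechanics:
    def test_maxpool_ceil_keeps_odd_tail(self, rng):
        pool = nn.MaxPool1D(2)
        x = rng.standard_normal((2, 3, 7))
        y = pool.forward(x)
        assert y.shape == (2, 3, 4)
        np.testing.assert_array_equal(y[..., -1], x[..., -1])  # lone tail survives
        g = pool.backward(np.ones_like(y))
        assert g.shape == x.shape
        assert g.sum() == y.size  # each output routes exactly one gradient unit

    def test_conv_same_padding_preserves_length(self, rng):
        for k in (1, 3, 8):
            conv = nn.Conv1D(2, 4, k, rng)
            y = conv.forward(rng.standard_normal((3, 2, 25)).astype(np.float32))
            assert y.shape == (3, 4, 25)

    def test_batchnorm_inference_tracks_batch_statistics(self, rng):
        bn = nn.BatchNorm(4)
        x = (rng.standard_normal((64, 4)) * 3 + 1).astype(np.float32)
        for _ in range(50):
            bn.forward(x, training=True)
        out = bn.forward(x, training=False)
        assert np.abs(out.mean(axis=0)).max() < 0.05
        assert np.abs(out.std(axis=0) - 1).max() < 0.1

    def test_dropout_inverted_scaling(self, rng):
        drop = nn.Dropout(0.25, rng)
        x = np.ones((200, 100), dtype=np.float32)
        y = drop.forward(x, training=True)
        assert abs(y.mean() - 1.0) < 0.02  # inverted dropout preserves the mean
        np.testing.assert_array_equal(drop.forward(x, training=False), x)

    def test_sigmoid_saturates_stably(self):
        s = nn.Sigmoid()
        y = s.forward(np.array([[-1000.0], [1000.0], [0.0]]))
        assert np.all(np.isfinite(y))
        np.testing.assert_allclose(y[:, 0], [0.0, 1.0, 0.5], atol=1e-12)

    def test_state_round_trip_and_shape_guard(self, rng):
        net = nn.Sequential([nn.Dense(4, 3, rng), nn.Dense(3, 1, rng)])
        arrays = [a.copy() for a in net.state_arrays()]
        net.load_state_arrays(arrays)
        with pytest.raises(ValueError, match="shape mismatch"):
            net.load_state_arrays([a.T.copy() for a in arrays])


class TestTraining:
    def test_adam_fits_separable_toy_problem(self, rng):
        x = rng.standard_normal((256, 10)).astype(np.float32)
        y = (x[:, :1] > 0).astype(np.float32)
        net = nn.Sequential([nn.Dense(10, 8, rng), nn.ReLU(),
                             nn.Dense(8, 1, rng), nn.Sigmoid()])
        opt = nn.Adam(net.params(), lr=1e-2)
        first = nn.bce_loss(net.forward(x, training=True), y)
        for _ in range(200):
            p = net.forward(x, training=True)
            net.backward(nn.bce_grad(p, y))
            opt.step()
        last = nn.bce_loss(net.forward(x, training=False), y)
        assert last < 0.1 < first
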