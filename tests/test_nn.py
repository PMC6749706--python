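"""Checks of the 3D-CNN building blocks against direct (loop-based) references."""

import numpy as np
import pytest

from gridpocket.nn import (
    Adam,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    Network,
    ReLU,
    binary_cross_entropy,
    sigmoid,
)


def _direct_conv(x, W, b, plo, phi):
    n, c, d, h, w = x.shape
    f, _, k, _, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (plo, phi), (plo, phi), (plo, phi)))
    y = np.zeros((n, f, d, h, w), dtype=np.float64)
    for ni in range(n):
        for fi in range(f):
            for di in range(d):
                for hi in range(h):
                    for wi in range(w):
                        y[ni, fi, di, hi, wi] = (
                            np.sum(xp[ni, :, di : di + k, hi : hi + k, wi : wi + k] * W[fi])
                            + b[fi]
                        )
    return y


class TestConv3D:
    @pytest.mark.parametrize("k", [2, 3, 4, 8])
    def test_forward_matches_direct_correlation(self, k, rng):
        d = 10 if k == 8 else 6
        conv = Conv3D(3, 2, k, rng)
        x = rng.normal(size=(2, 3, d, d, d)).astype(np.float32)
        y = conv.forward(x)
        ref = _direct_conv(x, conv.W.astype(np.float64), conv.b, conv.plo, conv.phi)
        np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-5)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_backward_matches_direct_gradients(self, k, rng):
        d = 10 if k == 8 else 6
        conv = Conv3D(2, 2, k, rng)
        x = rng.normal(size=(2, 2, d, d, d)).astype(np.float32)
        y = conv.forward(x, train=True)
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = conv.backward(dy)
        plo, phi = conv.plo, conv.phi
        xp = np.pad(x, ((0, 0), (0, 0), (plo, phi), (plo, phi), (plo, phi)))
        dW = np.zeros_like(conv.W, dtype=np.float64)
        for fi in range(2):
            for ci in range(2):
                for a in range(k):
                    for b_ in range(k):
                        for c_ in range(k):
                            dW[fi, ci, a, b_, c_] = np.sum(
                                dy[:, fi] * xp[:, ci, a : a + d, b_ : b_ + d, c_ : c_ + d]
                            )
        dxp = np.zeros_like(xp, dtype=np.float64)
        for ni in range(2):
            for fi in range(2):
                for di in range(d):
                    for hi in range(d):
                        for wi in range(d):
                            dxp[ni, :, di : di + k, hi : hi + k, wi : wi + k] += (
                                dy[ni, fi, di, hi, wi] * conv.W[fi]
                            )
        np.testing.assert_allclose(conv.dW, dW, rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose(
            dx, dxp[:, :, plo : plo + d, plo : plo + d, plo : plo + d], rtol=1e-4, atol=1e-5
        )
        np.testing.assert_allclose(conv.db, dy.sum(axis=(0, 2, 3, 4)), rtol=1e-4)


class TestMaxPool:
    def test_forward_and_gradient_routing(self, rng):
        pool = MaxPool3D()
        x = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        y = pool.forward(x)
        assert y.shape == (1, 1, 2, 2, 2)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    assert y[0, 0, i, j, k] == x[0, 0, 2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2].max()
        dy = np.ones_like(y)
        dx = pool.backward(dy)
        assert dx.sum() == pytest.approx(8.0)  # one route per window
        assert np.all(dx[x != np.repeat(np.repeat(np.repeat(y, 2, 2), 2, 3), 2, 4)] == 0)


class TestDenseAndHead:
    def test_dense_gradients(self, rng):
        dense = Dense(5, 3, rng)
        x = rng.normal(size=(4, 5)).astype(np.float32)
        y = dense.forward(x)
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = dense.backward(dy)
        np.testing.assert_allclose(dense.dW, x.T @ dy, rtol=1e-5)
        np.testing.assert_allclose(dx, dy @ dense.W.T, rtol=1e-5)

    def test_sigmoid_bounds_and_bce(self):
        z = np.array([-100.0, 0.0, 100.0])
        p = sigmoid(z)
        assert 0 <= p.min() and p.max() <= 1 and p[1] == 0.5
        assert binary_cross_entropy(np.array([0.5]), np.array([1.0])) == pytest.approx(
            np.log(2)
        )


class TestDropout:
    def test_inference_is_identity_training_scales(self, rng):
        drop = Dropout(0.5)
        x = np.ones((4, 10), dtype=np.float32)
        assert np.array_equal(drop.forward(x, train=False, rng=rng), x)
        y = drop.forward(x, train=True, rng=rng)
        kept = y[y != 0]
        assert np.allclose(kept, 2.0)  # inverted scaling 1/(1-p)


class TestTraining:
    def _toy_net(self, rng):
        return Network(
            [Conv3D(1, 2, 2, rng), ReLU(), MaxPool3D(), Flatten(), Dense(2 * 2 * 2 * 2, 1, rng)],
            seed=0,
        )

    def test_overfits_separable_toy_data(self, rng):
        net = self._toy_net(rng)
        x = np.zeros((16, 1, 4, 4, 4), dtype=np.float32)
        y = (np.arange(16) % 2).astype(float)
        x[y == 1, 0, 1:3, 1:3, 1:3] = 1.0
        net.fit(x, y, epochs=200, batch_size=8, learning_rate=3e-3,
                patience=None, stop_at_accuracy=1.0)
        _, acc = net.evaluate(x, y)
        assert acc == 1.0

    def test_all_negative_labels_drive_predictions_to_zero(self, rng):
        net = self._toy_net(rng)
        x = rng.normal(size=(12, 1, 4, 4, 4)).astype(np.float32)
        y = np.zeros(12)
        net.fit(x, y, epochs=120, batch_size=6, learning_rate=3e-3, patience=None)
        assert net.predict_proba(x).max() < 0.2
        assert net.history[-1].loss < 0.1

    def test_early_stopping_on_plateau(self, rng):
        net = self._toy_net(rng)
        x = rng.normal(size=(8, 1, 4, 4, 4)).astype(np.float32)
        y = (np.arange(8) % 2).astype(float)
        xv = rng.normal(size=(8, 1, 4, 4, 4)).astype(np.float32)  # unlearnable val
        yv = (rng.random(8) > 0.5).astype(float)
        net.fit(x, y, validation=(xv, yv), epochs=100, batch_size=4, patience=3)
        assert len(net.history) < 100

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(8, 1, 4, 4, 4)).astype(np.float32)
        y = (np.arange(8) % 2).astype(float)
        runs = []
        for _ in range(2):
            r = np.random.default_rng(5)
            net = Network(
                [Conv3D(1, 2, 2, r), ReLU(), MaxPool3D(), Flatten(), Dense(16, 1, r)],
                seed=5,
            )
            net.fit(x, y, epochs=5, batch_size=4, patience=None)
            runs.append(net.predict_proba(x))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_save_load_roundtrip(self, tmp_path, rng):
        net = self._toy_net(rng)
        x = rng.normal(size=(4, 1, 4, 4, 4)).astype(np.float32)
        p1 = net.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        net2 = self._toy_net(np.random.default_rng(99))
        net2.load_weights(path)
        np.testing.assert_allclose(net2.predict_proba(x), p1, rtol=1e-6)
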