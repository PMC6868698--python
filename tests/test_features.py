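"""Descriptor layout and the convolutional encoder against brute-force oracles."""

import math

import numpy as np
import pytest

from drugrelink.dataio import SimilarityMatrix
from drugrelink.features import (
    ConvolutionalEncoder,
    EncoderConfig,
    binary_cross_entropy,
    build_pair_descriptor,
    build_descriptor_grids,
    conv2d_valid,
    grid_side,
    max_pool,
)


def brute_conv(grid, kernel, bias):
    """Sliding-window dot-product oracle for one grid and one kernel."""
    s = grid.shape[0]
    k = kernel.shape[0]
    out = np.zeros((s - k + 1, s - k + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = float((grid[i : i + k, j : j + k] * kernel).sum()) + bias
    return out


def brute_pool(m, p):
    """Block-maximum oracle (ceil mode)."""
    h, w = m.shape
    ph, pw = -(-h // p), -(-w // p)
    out = np.zeros((ph, pw))
    for i in range(ph):
        for j in range(pw):
            out[i, j] = m[i * p : (i + 1) * p, j * p : (j + 1) * p].max()
    return out


def _sim(n, prefix, seed):
    rng = np.random.default_rng(seed)
    v = rng.random((n, n)) * 0.9
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.99)
    return SimilarityMatrix([f"{prefix}{i}" for i in range(n)], v)


class TestDescriptorLayout:
    @pytest.mark.parametrize(
        "n_drugs,n_diseases,side,pads",
        [(593, 313, 31, 55), (4, 5, 3, 0), (663, 409, 33, 17)],
    )
    def test_grid_side_and_padding(self, n_drugs, n_diseases, side, pads):
        assert grid_side(n_drugs, n_diseases) == side
        assert side * side - (n_drugs + n_diseases) == pads

    def test_flatten_recovers_rows(self):
        rsim, sim = _sim(4, "d", 0), _sim(5, "e", 1)
        d = build_pair_descriptor(rsim, sim, "d2", "e3")
        flat = d.grid.ravel()
        assert np.array_equal(flat[:4], rsim.row("d2"))
        assert np.array_equal(flat[4:9], sim.row("e3"))
        # padding cells are exactly zero
        assert np.all(flat[9:] == 0.0)
        assert d.grid.min() >= 0.0 and d.grid.max() <= 0.99

    def test_unknown_id_rejected(self):
        from drugrelink.dataio import IdentifierError

        rsim, sim = _sim(4, "d", 0), _sim(5, "e", 1)
        with pytest.raises(IdentifierError):
            build_pair_descriptor(rsim, sim, "nope", "e0")

    def test_batch_matches_single(self):
        rsim, sim = _sim(6, "d", 2), _sim(7, "e", 3)
        grids = build_descriptor_grids(rsim, sim, [("d1", "e2"), ("d5", "e0")])
        one = build_pair_descriptor(rsim, sim, "d5", "e0")
        assert np.array_equal(grids[1], one.grid)


class TestForwardOracles:
    def test_conv_matches_brute_force_16x16_on_20x20(self):
        rng = np.random.default_rng(0)
        grids = rng.random((3, 20, 20))
        kernels = rng.standard_normal((2, 16, 16))
        bias = rng.standard_normal(2)
        out = conv2d_valid(grids, kernels, bias)
        assert out.shape == (3, 5, 5, 2)
        for b in range(3):
            for f in range(2):
                expected = brute_conv(grids[b], kernels[f], bias[f])
                assert np.allclose(out[b, :, :, f], expected, atol=1e-6)

    @pytest.mark.parametrize("h,w,p", [(8, 8, 2), (5, 5, 2), (7, 4, 3)])
    def test_max_pool_matches_block_oracle(self, h, w, p):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((2, h, w, 3))
        out = max_pool(maps, p)
        for b in range(2):
            for f in range(3):
                assert np.array_equal(out[b, :, :, f], brute_pool(maps[b, :, :, f], p))

    def test_manual_single_filter_forward_pass(self):
        # 16x16 grid, 16x16 kernel -> 1x1 conv map; dense width 1 makes the
        # whole network a closed-form composition of sigmoids.
        rng = np.random.default_rng(2)
        grid = rng.random((16, 16))
        cfg = EncoderConfig(conv_kernel=16, n_filters=1, dense_units=1, epochs=0, seed=0)
        enc = ConvolutionalEncoder(cfg, 16)
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        a1 = sig(float((grid * enc.Wc[0]).sum()) + enc.bc[0])
        a2 = sig(a1 * enc.W1[0, 0] + enc.b1[0])
        out = sig(a2 * enc.W2[0, 0] + enc.b2[0])
        assert enc.encode(grid[None])[0, 0] == pytest.approx(a2, abs=1e-12)
        assert enc.predict_proba(grid[None])[0] == pytest.approx(out, abs=1e-12)

    def test_zero_weight_encoder_outputs_sigmoid_bias(self):
        cfg = EncoderConfig(conv_kernel=4, n_filters=2, dense_units=3, epochs=0, seed=0)
        enc = ConvolutionalEncoder(cfg, 8)
        enc.Wc[:] = 0.0
        enc.W1[:] = 0.0
        enc.b1[:] = 0.7
        feats = enc.encode(np.zeros((2, 8, 8)))
        assert np.allclose(feats, 1.0 / (1.0 + np.exp(-0.7)))


class TestLossAndTraining:
    def _toy(self, n=60, side=8, seed=3):
        # labels depend on a planted 2x2 block of the grid
        rng = np.random.default_rng(seed)
        grids = rng.random((n, side, side)) * 0.3
        y = rng.integers(0, 2, size=n)
        grids[y == 1, 2:4, 2:4] += 0.6
        return grids, y

    def test_l2_zero_loss_is_plain_bce(self):
        grids, y = self._toy()
        cfg = EncoderConfig(conv_kernel=4, epochs=0, l2=0.0, seed=0)
        enc = ConvolutionalEncoder(cfg, 8)
        probs = enc.predict_proba(grids)
        assert enc.loss(grids, y) == pytest.approx(binary_cross_entropy(probs, y), abs=1e-9)

    def test_l2_penalty_added(self):
        grids, y = self._toy()
        enc0 = ConvolutionalEncoder(EncoderConfig(conv_kernel=4, epochs=0, l2=0.0, seed=0), 8)
        enc1 = ConvolutionalEncoder(EncoderConfig(conv_kernel=4, epochs=0, l2=0.1, seed=0), 8)
        w2 = (enc0.Wc ** 2).sum() + (enc0.W1 ** 2).sum() + (enc0.W2 ** 2).sum()
        assert enc1.loss(grids, y) - enc0.loss(grids, y) == pytest.approx(0.05 * w2, rel=1e-9)

    def test_training_reduces_loss_on_learnable_toy(self):
        grids, y = self._toy()
        cfg = EncoderConfig(conv_kernel=4, epochs=30, seed=0)
        enc = ConvolutionalEncoder(cfg, 8).fit(grids, y)
        assert enc.loss_history[-1] < enc.loss_history[0]

    def test_sgd_variant_also_trains(self):
        grids, y = self._toy()
        cfg = EncoderConfig(conv_kernel=4, epochs=30, optimizer="sgd", lr=0.5, seed=0)
        enc = ConvolutionalEncoder(cfg, 8).fit(grids, y)
        assert enc.loss_history[-1] < enc.loss_history[0]

    def test_same_seed_bit_identical(self):
        grids, y = self._toy()
        cfg = EncoderConfig(conv_kernel=4, epochs=5, seed=11)
        f1 = ConvolutionalEncoder(cfg, 8).fit(grids, y).encode(grids)
        f2 = ConvolutionalEncoder(cfg, 8).fit(grids, y).encode(grids)
        assert np.array_equal(f1, f2)

    def test_encode_is_pure(self):
        grids, y = self._toy()
        enc = ConvolutionalEncoder(EncoderConfig(conv_kernel=4, epochs=2, seed=0), 8).fit(grids, y)
        assert np.array_equal(enc.encode(grids), enc.encode(grids))

    def test_feature_values_in_unit_interval_and_fixed_length(self):
        grids, y = self._toy()
        cfg = EncoderConfig(conv_kernel=4, dense_units=7, epochs=2, seed=0)
        feats = ConvolutionalEncoder(cfg, 8).fit(grids, y).encode(grids)
        assert feats.shape == (len(grids), 7)
        assert np.all((feats > 0) & (feats < 1))

    def test_single_class_labels_rejected(self):
        grids, _ = self._toy()
        enc = ConvolutionalEncoder(EncoderConfig(conv_kernel=4, epochs=1, seed=0), 8)
        with pytest.raises(ValueError, match="both classes"):
            enc.fit(grids, np.ones(len(grids)))

    def test_kernel_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            ConvolutionalEncoder(EncoderConfig(conv_kernel=16, seed=0), 10)

    def test_gradients_match_finite_differences(self):
        # exactness of backprop on a tiny network, central differences oracle
        rng = np.random.default_rng(4)
        grids = rng.random((6, 6, 6))
        y = np.array([0, 1, 0, 1, 1, 0])
        cfg = EncoderConfig(conv_kernel=3, n_filters=2, dense_units=3, epochs=0,
                            l2=1e-3, seed=0)
        enc = ConvolutionalEncoder(cfg, 6)
        grads = enc._gradients(grids, y.astype(float))
        params = [enc.Wc, enc.bc, enc.W1, enc.b1, enc.W2, enc.b2]
        eps = 1e-6
        for p, g in zip(params, grads):
            idx = tuple(0 for _ in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = enc.loss(grids, y)
            p[idx] = orig - eps
            lm = enc.loss(grids, y)
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-7)
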