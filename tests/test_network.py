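"""Network layers against brute-force oracles; training protocol logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uctnet.network import (
    Model,
    NetworkSpec,
    SplitIndices,
    TrainConfig,
    build_network,
    conv2d_ref,
    leaky_relu,
    max_pool,
    mse_loss,
    predict,
    split_dataset,
    train,
)


def brute_force_conv(image, kernel, bias, slope):
    """Nested-loop evaluation of the same-padded conv + leaky ReLU."""
    H, W = image.shape
    L = kernel.shape[0]
    p = L // 2
    out = np.zeros((H, W))
    for m in range(H):
        for n in range(W):
            acc = bias
            for u in range(L):
                for v in range(L):
                    mm, nn = m + u - p, n + v - p
                    if 0 <= mm < H and 0 <= nn < W:
                        acc += kernel[u, v] * image[mm, nn]
            out[m, n] = acc if acc >= 0 or slope is None else slope * acc
    return out


class TestConvOracle:
    def test_identity_kernel(self):
        x = np.abs(np.random.default_rng(0).normal(size=(6, 6))) + 0.1
        out = conv2d_ref(x, np.array([[1.0]]), 0.0, 0.01)
        assert np.allclose(out, x)

    def test_zero_weights_bias_only(self):
        out = conv2d_ref(np.ones((5, 5)), np.zeros((3, 3)), 2.5, 0.01)
        assert np.all(out == 2.5)

    @pytest.mark.parametrize("L", [1, 3, 5])
    def test_reference_matches_nested_loops_float(self, L):
        rng = np.random.default_rng(L)
        for _ in range(30):
            x = rng.normal(size=(5, 5))
            k = rng.normal(size=(L, L))
            b = float(rng.normal())
            assert np.allclose(conv2d_ref(x, k, b, 0.01),
                               brute_force_conv(x, k, b, 0.01), atol=1e-12)

    def test_reference_matches_nested_loops_integer_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.integers(-5, 6, size=(6, 6)).astype(float)
            k = rng.integers(-3, 4, size=(3, 3)).astype(float)
            assert np.array_equal(conv2d_ref(x, k, 0.0, None),
                                  brute_force_conv(x, k, 0.0, None))

    def test_fast_layer_matches_reference(self):
        """The batched im2col path equals the per-pixel reference, layer by
        layer, on random inputs (float64, <= 1e-12)."""
        rng = np.random.default_rng(4)
        spec = NetworkSpec(input_size=8, hidden=((3, 3), (2, 5), (2, 3), (2, 3)),
                           pool_after=4, output_grid=(8, 8, 1))
        m = build_network(spec, seed=1, weight_init="scaled", dtype="float64")
        x = rng.normal(size=(1, 1, 8, 8))
        layer = m.layers[0]  # first conv: 3 kernels of 3x3 on 1 channel
        fast = layer.forward(x, keep=False)
        for c in range(3):
            ref = conv2d_ref(x[0, 0], layer.W[c, 0], float(layer.b[c]), spec.leaky_slope)
            assert np.allclose(fast[0, c], ref, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv2d_ref(np.ones((5, 5)), np.ones((2, 2)))


class TestLeakyRelu:
    @pytest.mark.parametrize("x,slope,expect", [(2.0, 0.01, 2.0), (-2.0, 0.01, -0.02),
                                                (-5.0, 0.0, 0.0), (0.0, 0.3, 0.0)])
    def test_values(self, x, slope, expect):
        assert leaky_relu(x, slope) == pytest.approx(expect)

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            leaky_relu(1.0, 1.5)


class TestMaxPool:
    def test_tiny_window(self):
        assert max_pool(np.array([[1.0, 3.0], [2.0, 4.0]]), 2).tolist() == [[4.0]]

    def test_constant_map(self):
        out = max_pool(np.full((6, 6), 2.0), 2)
        assert out.shape == (3, 3) and np.all(out == 2.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 3), st.integers(1, 3))
    def test_matches_window_scan(self, seed, window, stride):
        x = np.random.default_rng(seed).normal(size=(8, 8))
        out = max_pool(x, window, stride)
        H = (8 - window) // stride + 1
        assert out.shape == (H, H)
        for i in range(H):
            for j in range(H):
                block = x[i * stride : i * stride + window, j * stride : j * stride + window]
                assert out[i, j] == block.max()

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            max_pool(np.ones((4, 4)), 5)


class TestMseLoss:
    def test_identical_zero(self):
        x = np.random.default_rng(0).normal(size=(7, 7))
        assert mse_loss(x, x) == 0.0

    def test_unit_offset(self):
        x = np.zeros((4, 4))
        assert mse_loss(x + 1.0, x) == pytest.approx(1.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(size=(6, 5))
            b = rng.normal(size=(6, 5))
            direct = sum((a[i, j] - b[i, j]) ** 2 for i in range(6) for j in range(5)) / 30
            assert mse_loss(a, b) == pytest.approx(direct, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBuildNetwork:
    def test_full_scale_head_has_100_kernels(self):
        """A 240 x 200 x 100 output volume needs one output kernel per slice."""
        spec = NetworkSpec(input_size=512, output_grid=(240, 200, 100))
        m = build_network(spec, seed=0)
        out_conv = m.layers[-1]
        assert out_conv.W.shape[0] == 100
        assert spec.output_channels == 100

    def test_same_seed_identical_weights(self):
        spec = NetworkSpec(input_size=16, output_grid=(32, 32, 1))
        a = build_network(spec, seed=7)
        b = build_network(spec, seed=7)
        for pa, pb in zip(a.parameters, b.parameters):
            assert np.array_equal(pa, pb)

    def test_2d_mode_single_output_kernel(self):
        m = build_network(NetworkSpec(input_size=16, output_grid=(32, 32, 1)), seed=0)
        assert m.layers[-1].W.shape[0] == 1

    def test_default_init_is_uniform_0_1(self):
        m = build_network(NetworkSpec(input_size=16, output_grid=(32, 32, 1)), seed=0)
        W = m.layers[0].W
        assert W.min() >= 0.0 and W.max() <= 1.0 and W.std() > 0.1

    def test_nonstandard_depth_warns(self):
        with pytest.warns(UserWarning):
            NetworkSpec(input_size=16, hidden=((8, 3), (8, 3)), pool_after=1,
                        output_grid=(16, 16, 1))


class TestSplitDataset:
    @pytest.mark.parametrize("n,expect", [(700, (420, 140, 140)), (401, (240, 81, 80)),
                                          (5, (3, 1, 1))])
    def test_published_split_sizes(self, n, expect):
        s = split_dataset(n, seed=0)
        assert (s.train.size, s.validation.size, s.test.size) == expect

    @settings(deadline=None, max_examples=50)
    @given(st.integers(5, 2000), st.integers(0, 2**31 - 1))
    def test_disjoint_and_covering(self, n, seed):
        s = split_dataset(n, seed=seed)
        allidx = np.concatenate([s.train, s.validation, s.test])
        assert np.array_equal(np.sort(allidx), np.arange(n))

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            SplitIndices(train=np.array([0, 1]), validation=np.array([1]),
                         test=np.array([2]), ratios=(0.6, 0.2, 0.2), seed=0)


def _toy_problem(n=10, size=8, out=12, seed=0):
    """Random inputs with smooth random velocity-map labels (coarse noise,
    bilinearly upsampled — the spatial smoothness real velocity maps have)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, size, size))
    coarse = rng.uniform(1400.0, 2600.0, size=(n, 4, 4))
    rep = -(-out // 4)  # block-upsample then crop
    Y = np.repeat(np.repeat(coarse, rep, axis=1), rep, axis=2)[:, :out, :out]
    return X, Y


class TestTraining:
    def test_default_protocol_constants(self):
        cfg = TrainConfig()
        assert (cfg.batch_size, cfg.max_epochs, cfg.early_stop_patience) == (8, 5000, 500)

    def test_two_sample_memorization(self):
        """Enough epochs on two samples drives training MSE below 1e-4.

        Labels come from a same-architecture teacher network, so an exact
        zero-loss solution exists and the only question is whether the
        optimizer finds it (overfit sanity check)."""
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(10, 8, 8))
        spec = NetworkSpec(input_size=8, hidden=((32, 5), (32, 5), (32, 3), (32, 3)),
                           pool_after=2, output_grid=(12, 12, 1))
        teacher = build_network(spec, seed=99, weight_init="scaled", dtype="float64")
        Yn = teacher.forward(X[:, None, :, :])[:, 0]
        Y = 1400.0 + 1200.0 * (Yn - Yn.min()) / (Yn.max() - Yn.min())
        m = build_network(spec, seed=0, weight_init="scaled", dtype="float64")
        split = SplitIndices(train=np.array([0, 1]), validation=np.array([2]),
                             test=np.array([3]), ratios=(0.6, 0.2, 0.2), seed=0)
        cfg = TrainConfig(batch_size=2, max_epochs=1500, early_stop_patience=1499,
                          learning_rate=1e-2, seed=0, weight_init="scaled",
                          dtype="float64")
        train(m, list(X), list(Y), split, cfg)
        assert min(m.history["train_mse"]) < 1e-4

    def test_patience_one_frozen_lr_stops_after_two_epochs(self):
        X, Y = _toy_problem()
        spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                           pool_after=2, output_grid=(12, 12, 1))
        m = build_network(spec, seed=0, weight_init="scaled")
        split = split_dataset(10, seed=0)
        cfg = TrainConfig(batch_size=4, max_epochs=100, early_stop_patience=1,
                          learning_rate=0.0, seed=0, weight_init="scaled")
        train(m, list(X), list(Y), split, cfg)
        # epoch 1 sets the best; epoch 2 cannot improve (lr=0) -> stop at 2
        assert len(m.history["val_mse"]) == 2

    def test_best_epoch_is_validation_minimum(self):
        X, Y = _toy_problem()
        spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                           pool_after=2, output_grid=(12, 12, 1))
        m = build_network(spec, seed=1, weight_init="scaled")
        cfg = TrainConfig(batch_size=4, max_epochs=30, early_stop_patience=29,
                          seed=1, weight_init="scaled")
        train(m, list(X), list(Y), split_dataset(10, seed=0), cfg)
        hist = np.array(m.history["val_mse"])
        assert hist[m.best_epoch - 1] == hist.min()

    def test_seeded_reproducibility(self):
        X, Y = _toy_problem()
        spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                           pool_after=2, output_grid=(12, 12, 1))
        hists = []
        for _ in range(2):
            m = build_network(spec, seed=5, weight_init="scaled")
            cfg = TrainConfig(batch_size=4, max_epochs=10, early_stop_patience=9,
                              seed=5, weight_init="scaled")
            train(m, list(X), list(Y), split_dataset(10, seed=0), cfg)
            hists.append(m.history["val_mse"])
        assert hists[0] == hists[1]

    def test_misaligned_inputs_rejected(self):
        X, Y = _toy_problem()
        spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                           pool_after=2, output_grid=(12, 12, 1))
        m = build_network(spec, seed=0)
        with pytest.raises(ValueError):
            train(m, list(X)[:-1], list(Y), split_dataset(10, seed=0), TrainConfig())


@pytest.fixture(scope="module")
def trained_predictor():
    X, Y = _toy_problem()
    spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                       pool_after=2, output_grid=(12, 10, 1))
    m = build_network(spec, seed=2, weight_init="scaled")
    Y10 = [y[:, :10] for y in Y]
    cfg = TrainConfig(batch_size=4, max_epochs=20, early_stop_patience=19,
                      seed=2, weight_init="scaled")
    return train(m, list(X), Y10, split_dataset(10, seed=0), cfg), X


class TestPredict:
    def test_output_shape_matches_grid(self, trained_predictor):
        m, X = trained_predictor
        assert predict(m, X[0]).shape == (12, 10)

    def test_deterministic(self, trained_predictor):
        m, X = trained_predictor
        assert np.array_equal(predict(m, X[0]), predict(m, X[0]))

    def test_outputs_within_velocity_bounds(self, trained_predictor):
        m, X = trained_predictor
        lo, hi = m.velocity_bounds
        for x in X:
            out = predict(m, x)
            assert out.min() >= lo - 1e-6 and out.max() <= hi + 1e-6

    def test_wrong_size_rejected(self, trained_predictor):
        m, _ = trained_predictor
        with pytest.raises(ValueError):
            predict(m, np.ones((9, 9)))

    def test_untrained_model_rejected(self):
        m = build_network(NetworkSpec(input_size=8, output_grid=(12, 12, 1)), seed=0)
        with pytest.raises(ValueError):
            predict(m, np.ones((8, 8)))

    def test_3d_output_shape(self):
        X, _ = _toy_problem()
        rng = np.random.default_rng(0)
        Y3 = [rng.uniform(1400, 2600, size=(10, 9, 4)) for _ in range(10)]
        spec = NetworkSpec(input_size=8, hidden=((4, 3), (4, 3), (4, 3), (4, 3)),
                           pool_after=2, output_grid=(10, 9, 4))
        m = build_network(spec, seed=0, weight_init="scaled")
        cfg = TrainConfig(batch_size=4, max_epochs=3, early_stop_patience=2,
                          seed=0, weight_init="scaled")
        train(m, list(X), Y3, split_dataset(10, seed=0), cfg)
        assert predict(m, X[0]).shape == (10, 9, 4)
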