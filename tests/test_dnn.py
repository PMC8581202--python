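import numpy as np
import pytest
from hypothesis import given, strategies as st

from mibci import DNNParams, backprop, forward, init_params, mse_loss, train_dnn
from mibci.dnn import ACTIVATIONS, pretrain_autoencoders


def numeric_gradient(p, x, y, eps=1e-5):
    """Central finite differences of the half-squared-error loss over every
    parameter; independent of the backprop code path."""
    grads = []
    for h in range(p.n_layers):
        W, b = p.layers[h]
        dW, db = np.zeros_like(W), np.zeros_like(b)
        for arr, darr in ((W, dW), (b, db)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                hi = mse_loss(forward(p, x)[-1], y)
                arr[idx] = orig - eps
                lo = mse_loss(forward(p, x)[-1], y)
                arr[idx] = orig
                darr[idx] = (hi - lo) / (2 * eps)
        grads.append((dW, db))
    return grads


def rel_error(analytic, numeric):
    num = np.abs(analytic - numeric)
    den = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-8)
    return (num / den).max()


class TestForward:
    def test_zero_params_sigmoid_gives_half(self):
        p = DNNParams(layers=[(np.zeros((3, 2)), np.zeros(3)), (np.zeros((2, 3)), np.zeros(2))])
        acts = forward(p, np.array([0.7, -1.2]))
        assert all(np.all(a == 0.5) for a in acts)

    def test_identity_two_layer_composes_linearly(self):
        w1, w2, x = 3.0, -0.5, 1.7
        p = DNNParams(
            layers=[(np.array([[w1]]), np.zeros(1)), (np.array([[w2]]), np.zeros(1))],
            activation="identity",
        )
        assert forward(p, np.array([x]))[-1][0] == pytest.approx(w2 * w1 * x)

    @pytest.mark.parametrize("activation", sorted(ACTIVATIONS))
    def test_matches_handrolled_recurrence(self, activation, rng):
        p = init_params([4, 5, 3, 2], activation, seed=7)
        x = rng.standard_normal(4)
        # independent scalar-loop evaluation of a^h = act(W a + b)
        act = ACTIVATIONS[activation][0]
        a = x
        expected = []
        for W, b in p.layers:
            z = np.array([sum(W[j, k] * a[k] for k in range(len(a))) + b[j]
                          for j in range(W.shape[0])])
            a = act(z)
            expected.append(a)
        got = forward(p, x)
        for e, g in zip(expected, got):
            assert np.allclose(e, g, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = init_params([4, 3], seed=0)
        with pytest.raises(ValueError, match="dimension"):
            forward(p, np.zeros(5))

    def test_shape_chain_validated(self):
        with pytest.raises(ValueError, match="layer 1"):
            DNNParams(layers=[(np.zeros((3, 2)), np.zeros(3)), (np.zeros((2, 4)), np.zeros(2))])


class TestMSELoss:
    def test_equal_vectors_zero(self):
        assert mse_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_unit_example(self):
        assert mse_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_matches_direct_summation(self, rng):
        a, y = rng.standard_normal(9), rng.standard_normal(9)
        direct = sum((ai - yi) ** 2 for ai, yi in zip(a, y)) / 2
        assert mse_loss(a, y) == pytest.approx(direct, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mse_loss(np.zeros(2), np.zeros(3))


class TestBackprop:
    def test_single_linear_unit_closed_form(self):
        w, b, x, y = 1.5, -0.3, 2.0, 0.25
        p = DNNParams(layers=[(np.array([[w]]), np.array([b]))], activation="identity")
        g = backprop(p, np.array([x]), np.array([y]))
        err = w * x + b - y
        assert g.layers[0][0][0, 0] == pytest.approx(err * x)
        assert g.layers[0][1][0] == pytest.approx(err)

    def test_exact_output_gives_zero_gradients(self, rng):
        p = init_params([3, 4, 2], "sigmoid", seed=5)
        x = rng.standard_normal(3)
        y = forward(p, x)[-1]  # target = achieved output -> delta^H = 0
        g = backprop(p, x, y)
        assert all(np.all(dW == 0) and np.all(db == 0) for dW, db in g.layers)

    @pytest.mark.parametrize("activation", sorted(ACTIVATIONS))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, activation, seed):
        rng = np.random.default_rng(seed)
        sizes = [int(rng.integers(2, 5)) for _ in range(int(rng.integers(3, 5)))]
        p = init_params(sizes, activation, seed=seed)
        x = rng.standard_normal(sizes[0])
        y = rng.standard_normal(sizes[-1])
        analytic = backprop(p, x, y)
        numeric = numeric_gradient(p, x, y)
        for (adW, adb), (ndW, ndb) in zip(analytic.layers, numeric):
            assert rel_error(adW, ndW) < 1e-6
            assert rel_error(adb, ndb) < 1e-6

    @given(seed=st.integers(0, 1000))
    def test_gradient_check_randomized_shapes(self, seed):
        rng = np.random.default_rng(seed)
        activation = ["sigmoid", "relu", "identity"][seed % 3]
        sizes = [int(rng.integers(1, 5)) for _ in range(int(rng.integers(2, 5)))]
        p = init_params(sizes, activation, seed=seed)
        # keep relu away from its kink, where finite differences are invalid
        x = rng.standard_normal(sizes[0]) + 0.05
        y = rng.standard_normal(sizes[-1])
        analytic = backprop(p, x, y)
        numeric = numeric_gradient(p, x, y)
        worst = max(
            max(rel_error(adW, ndW), rel_error(adb, ndb))
            for (adW, adb), (ndW, ndb) in zip(analytic.layers, numeric)
        )
        assert worst < 1e-5


class TestTrainDNN:
    def test_zero_iterations_identity(self, blob_features):
        p = init_params([3, 4, 2], seed=0)
        targets = np.column_stack([blob_features.y == 1, blob_features.y == -1]).astype(float)
        out, losses = train_dnn(p, blob_features, targets, lr=0.1, iters=0)
        assert losses.size == 0
        for (W0, b0), (W1, b1) in zip(p.layers, out.layers):
            assert np.array_equal(W0, W1) and np.array_equal(b0, b1)

    def test_loss_decreases_on_separable_blobs(self, blob_features):
        p = init_params([3, 4, 2], seed=0)
        targets = np.column_stack([blob_features.y == 1, blob_features.y == -1]).astype(float)
        _, losses = train_dnn(p, blob_features, targets, lr=0.07, iters=2500)
        assert losses[-1] < losses[0]

    def test_identity_activation_loss_nonincreasing(self, rng):
        # convex case: full-batch descent with small lr never increases
        X = rng.standard_normal((30, 3))
        T = rng.standard_normal((30, 2))
        p = init_params([3, 2], "identity", seed=1)
        _, losses = train_dnn(p, X, T, lr=0.01, iters=200)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_same_seed_bitwise_identical(self, blob_features):
        targets = np.column_stack([blob_features.y == 1, blob_features.y == -1]).astype(float)
        runs = []
        for _ in range(2):
            p = init_params([3, 5, 2], seed=42)
            out, losses = train_dnn(p, blob_features, targets, lr=0.07, iters=50,
                                    batch_size=16, seed=9)
            runs.append((out, losses))
        assert np.array_equal(runs[0][1], runs[1][1])
        for (W0, b0), (W1, b1) in zip(runs[0][0].layers, runs[1][0].layers):
            assert np.array_equal(W0, W1) and np.array_equal(b0, b1)

    def test_divergence_aborts_with_iteration_number(self, rng):
        X = 100 * rng.standard_normal((10, 2))
        T = rng.standard_normal((10, 1))
        p = init_params([2, 1], "identity", seed=0)
        with pytest.raises(FloatingPointError, match="iteration"):
            train_dnn(p, X, T, lr=1e6, iters=100)

    def test_target_row_mismatch_rejected(self, rng):
        p = init_params([2, 1], seed=0)
        with pytest.raises(ValueError, match="targets"):
            train_dnn(p, rng.standard_normal((5, 2)), np.zeros((4, 1)), lr=0.1, iters=1)


class TestSymmetryAndPretrain:
    def test_swapping_targets_and_output_rows_mirrors_hidden_stack(self, blob_features):
        """Flipping all labels = swapping one-hot target columns; if the
        temporary output head's init rows are swapped too, the hidden stack
        trains to exactly the same weights."""
        T = np.column_stack([blob_features.y == 1, blob_features.y == -1]).astype(float)
        p = init_params([3, 4, 2], seed=3)
        p_swapped = p.copy()
        W, b = p_swapped.layers[-1]
        p_swapped.layers[-1] = (W[::-1].copy(), b[::-1].copy())
        out_a, _ = train_dnn(p, blob_features, T, lr=0.07, iters=300)
        out_b, _ = train_dnn(p_swapped, blob_features, T[:, ::-1], lr=0.07, iters=300)
        for (Wa, ba), (Wb, bb) in zip(out_a.layers[:-1], out_b.layers[:-1]):
            assert np.allclose(Wa, Wb, atol=1e-12)
            assert np.allclose(ba, bb, atol=1e-12)

    def test_autoencoder_pretraining_shapes_and_determinism(self, blob_features):
        a = pretrain_autoencoders([3, 5, 2], blob_features.X, seed=4, iters=30)
        b = pretrain_autoencoders([3, 5, 2], blob_features.X, seed=4, iters=30)
        assert a.sizes == [3, 5, 2]
        for (Wa, ba), (Wb, bb) in zip(a.layers, b.layers):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)
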