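"""Network primitives: He init, forward pass, loss, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import palpaid as p
from palpaid.network import _gradients


SMALL = p.ArchitectureConfig(input_dim=4, hidden_dims=(8, 8, 8))


def _hand_forward(params, x):
    """Independent oracle: explicit affine + ReLU + logistic arithmetic."""
    h = x
    for W, b in zip(params.weights[:3], params.biases[:3]):
        h = np.maximum(W @ h + b, 0.0)
    z = params.weights[3] @ h + params.biases[3]
    return 1.0 / (1.0 + np.exp(-z))


def test_he_initialization_statistics():
    arch = p.ArchitectureConfig()  # full scale: fan_in 1000 -> 2000x1000 W1
    params = p.init_params(arch, np.random.default_rng(0))
    w1 = params.weights[0]
    assert w1.shape == (2000, 1000)
    assert w1.std() == pytest.approx(np.sqrt(2.0 / 1000), rel=0.02)
    assert abs(w1.mean()) < 3 * np.sqrt(2.0 / 1000) / np.sqrt(w1.size)
    assert all((b == 0).all() for b in params.biases)


def test_init_is_deterministic_under_seed():
    a = p.init_params(SMALL, np.random.default_rng(7))
    b = p.init_params(SMALL, np.random.default_rng(7))
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_forward_matches_hand_rolled_oracle():
    rng = np.random.default_rng(3)
    params = p.init_params(SMALL, rng)
    for _ in range(5):
        x = rng.normal(size=4)
        np.testing.assert_allclose(p.forward(params, x), _hand_forward(params, x),
                                   atol=1e-12)


def test_zero_params_give_one_half_everywhere():
    params = p.ModelParams([np.zeros((8, 4)), np.zeros((8, 8)),
                            np.zeros((8, 8)), np.zeros((4, 8))],
                           [np.zeros(8), np.zeros(8), np.zeros(8), np.zeros(4)])
    np.testing.assert_allclose(p.forward(params, np.ones(4)), 0.5)


def test_relu_activation_values():
    params = p.init_params(SMALL, np.random.default_rng(0))
    assert max(-3.0, 0.0) == 0.0 and max(2.0, 0.0) == 2.0  # activation rule
    y = p.forward(params, np.array([1.0, -1.0, 0.5, 2.0]))
    assert ((y > 0) & (y < 1)).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), scale=st.sampled_from([1e-3, 1.0, 1e3]))
def test_forward_output_bounded_in_open_unit_interval(seed, scale):
    rng = np.random.default_rng(seed)
    params = p.init_params(SMALL, rng)
    x = rng.normal(size=(3, 4)) * scale
    y = p.forward(params, x)
    assert np.isfinite(y).all()
    assert ((y > 0) & (y < 1)).all()


def test_paper_sign_flag_flips_output():
    params = p.init_params(SMALL, np.random.default_rng(1))
    x = np.ones(4)
    np.testing.assert_allclose(p.forward(params, x, paper_sign=True),
                               1.0 - p.forward(params, x), atol=1e-12)


class TestLoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.array([1.0, 0.0])
        y = np.array([1.0 - 1e-12, 1e-12])
        assert p.loss(y, t) == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_gives_ln2(self):
        for mode in ("binary_cross_entropy", "positive_only"):
            assert p.loss(np.array([0.5]), np.array([1.0]), mode) == \
                pytest.approx(np.log(2))

    def test_modes_differ_by_negative_class_term(self):
        t = np.array([1.0, 0.0])
        y = np.array([0.5, 0.9])
        assert p.loss(y, t, "positive_only") == pytest.approx(np.log(2))
        assert p.loss(y, t, "binary_cross_entropy") == \
            pytest.approx(np.log(2) + np.log(10))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p.loss(np.array([0.5, 0.5]), np.array([1.0]))


@pytest.mark.parametrize("mode,paper_sign", [
    ("binary_cross_entropy", False),
    ("binary_cross_entropy", True),
    ("positive_only", False),
])
def test_analytic_gradients_match_finite_differences(mode, paper_sign):
    rng = np.random.default_rng(5)
    params = p.init_params(SMALL, rng)
    X = rng.normal(size=(3, 4))
    T = rng.integers(0, 2, size=(3, 4)).astype(float)
    gW, gb, _ = _gradients(params, X, T, mode, paper_sign)

    def f():
        from palpaid.network import _forward_cached
        y, _ = _forward_cached(params, X, paper_sign)
        return p.loss(y, T, mode)

    h = 1e-6
    for tensors, grads in ((params.weights, gW), (params.biases, gb)):
        for tensor, grad in zip(tensors, grads):
            flat = tensor.reshape(-1)
            k = min(10, flat.size)
            for idx in np.random.default_rng(0).choice(flat.size, k, replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = f()
                flat[idx] = orig - h
                down = f()
                flat[idx] = orig
                num = (up - down) / (2 * h)
                ana = grad.reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestTraining:
    def _toy(self, rng, n=60, d=8):
        T = rng.integers(0, 2, size=(n, d)).astype(float)
        X = T + 0.1 * rng.normal(size=(n, d))  # tumor samples offset by +1
        return X, T

    def test_loss_decreases_on_separable_toy_set(self):
        rng = np.random.default_rng(0)
        X, T = self._toy(rng)
        arch = p.ArchitectureConfig.scaled(8)
        params = p.init_params(arch, rng)
        cfg = p.TrainConfig(epochs=50, batch_size=20, seed=0)
        _, history = p.train(params, X, T, cfg)
        assert len(history) == 50
        assert history[-1] < history[0]

    def test_zero_epochs_leaves_params_unchanged(self):
        rng = np.random.default_rng(1)
        X, T = self._toy(rng)
        params = p.init_params(p.ArchitectureConfig.scaled(8), rng)
        out, history = p.train(params, X, T, p.TrainConfig(epochs=0, seed=0))
        assert history == []
        for w0, w1 in zip(params.weights, out.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_training_is_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X, T = self._toy(rng)
        arch = p.ArchitectureConfig.scaled(8)
        outs = []
        for _ in range(2):
            params = p.init_params(arch, np.random.default_rng(9))
            out, _ = p.train(params, X, T, p.TrainConfig(epochs=5, seed=4))
            outs.append(out)
        for wa, wb in zip(outs[0].weights, outs[1].weights):
            np.testing.assert_array_equal(wa, wb)


class TestEstimator:
    def test_fit_separates_classes_per_sample(self, participant_trials,
                                              desk_extraction):
        mats = [p.window_matrices(t, desk_extraction)
                for t in participant_trials[:10]]
        X = np.concatenate([m[0] for m in mats])
        T = np.concatenate([m[1] for m in mats])
        est = p.WindowSegmenterMLP(epochs=20, random_state=0)
        est.fit(X, T)
        Y = est.predict_proba(X)
        in_tumor = Y[T == 1].mean()
        out_tumor = Y[T == 0].mean()
        assert in_tumor > out_tumor  # class-conditional score separation

    def test_sklearn_params_roundtrip(self):
        est = p.WindowSegmenterMLP(epochs=7, random_state=3)
        clone_params = est.get_params()
        assert clone_params["epochs"] == 7
        est.set_params(epochs=9)
        assert est.epochs == 9

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            p.WindowSegmenterMLP().predict_proba(np.zeros((1, 4)))
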