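"""Network forward/backward correctness, optimizer and preprocessing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fedaffect import (
    AdamState,
    EmbeddingTable,
    ModelSpec,
    TrainConfig,
    accuracy,
    adam_step,
    augment_with_embedding,
    fit_standardizer,
    forward,
    gradient,
    init_params,
    loss,
    predict,
)
from fedaffect.model_core import ShapeError, _leaky, augment_rows


class TestInitParams:
    def test_deterministic_in_seed(self):
        spec = ModelSpec(32)
        assert init_params(spec, 7) == init_params(spec, 7)
        assert init_params(spec, 7) != init_params(spec, 8)

    def test_biases_start_at_zero(self):
        p = init_params(ModelSpec(32), 0)
        for k, v in p.arrays.items():
            if k.startswith("b"):
                assert np.all(v == 0)

    def test_weight_spread_shrinks_with_fan_in(self):
        # Monte-Carlo over 100 seeds: first-layer weights with fan-in 128
        # are tighter than with fan-in 8
        sds = {}
        for d in (8, 128):
            draws = [init_params(ModelSpec(d), s).arrays["W0"].std()
                     for s in range(100)]
            sds[d] = np.mean(draws)
        assert sds[128] < sds[8] / 2


class TestForward:
    def test_zero_params_give_uniform_probabilities(self):
        p = init_params(ModelSpec(5), 0)
        for k in p.arrays:
            p.arrays[k] = np.zeros_like(p.arrays[k])
        np.testing.assert_allclose(forward(p, np.ones(5)), [1/3, 1/3, 1/3],
                                   rtol=1e-12)

    def test_leaky_relu_slope(self):
        assert _leaky(np.array([-2.0]), 0.01)[0] == -0.02
        assert _leaky(np.array([2.0]), 0.01)[0] == 2.0

    def test_dimension_mismatch_raises(self):
        p = init_params(ModelSpec(5), 0)
        with pytest.raises(ShapeError):
            forward(p, np.ones(6))

    @given(st.integers(0, 50))
    def test_probabilities_sum_to_one(self, seed):
        p = init_params(ModelSpec(4), seed)
        rng = np.random.default_rng(seed)
        probs = forward(p, rng.normal(size=(6, 4)))
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestLoss:
    def test_closed_forms(self):
        assert loss(np.array([0.0, 1.0, 0.0]), 1) == pytest.approx(0.0)
        assert loss(np.array([1/3, 1/3, 1/3]), 2) == pytest.approx(np.log(3))
        assert loss(np.array([0.5, 0.25, 0.25]), 0) == pytest.approx(np.log(2))

    def test_batch_loss_is_row_mean(self):
        probs = np.array([[0.5, 0.25, 0.25], [1/3, 1/3, 1/3]])
        expected = (np.log(2) + np.log(3)) / 2
        assert loss(probs, [0, 1]) == pytest.approx(expected)

    def test_zero_probability_is_clipped(self, caplog):
        with caplog.at_level("WARNING", logger="fedaffect"):
            val = loss(np.array([1.0, 0.0, 0.0]), 1)
        assert val == pytest.approx(-np.log(1e-12))
        assert "clipped" in caplog.text


def finite_difference_grads(params, X, y, u, h=1e-6):
    """Central-difference oracle for the mean cross-entropy gradient."""
    out = {}
    for k, arr in params.arrays.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            arr[i] += h
            up = loss(forward(params, X), y)
            arr[i] -= 2 * h
            down = loss(forward(params, X), y)
            arr[i] += h
            g[i] = (up - down) / (2 * h)
        out[k] = g
    eg = None
    if u:
        eg = np.zeros((len(X), u))
        X = X.copy()
        for r in range(len(X)):
            for j in range(u):
                X[r, -u + j] += h
                up = loss(forward(params, X), y)
                X[r, -u + j] -= 2 * h
                down = loss(forward(params, X), y)
                X[r, -u + j] += h
                eg[r, j] = (up - down) / (2 * h)
    return out, eg


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        u = 2
        spec = ModelSpec(6 + u)
        params = init_params(spec, seed)
        X = rng.normal(size=(5, 6 + u))
        y = rng.integers(0, 3, size=5)
        grads, eg = gradient(params, X, y, embedding_dim=u)
        fd, fd_eg = finite_difference_grads(params, X, y, u)
        for k in grads:
            denom = np.maximum(np.abs(fd[k]), 1e-3)
            assert np.max(np.abs(grads[k] - fd[k]) / denom) < 1e-5
        denom = np.maximum(np.abs(fd_eg), 1e-3)
        assert np.max(np.abs(eg - fd_eg) / denom) < 1e-5

    def test_duplicating_rows_leaves_mean_gradient_unchanged(self, rng):
        params = init_params(ModelSpec(4), 3)
        X = rng.normal(size=(3, 4))
        y = np.array([0, 1, 2])
        g1, _ = gradient(params, X, y)
        g2, _ = gradient(params, np.vstack([X, X]), np.concatenate([y, y]))
        for k in g1:
            np.testing.assert_allclose(g1[k], g2[k], atol=1e-12)

    def test_zero_inputs_and_weights_give_zero_first_layer_gradient(self):
        params = init_params(ModelSpec(4), 0)
        for k in params.arrays:
            params.arrays[k] = np.zeros_like(params.arrays[k])
        g, _ = gradient(params, np.zeros((3, 4)), np.array([0, 1, 2]))
        assert np.all(g["W0"] == 0)

    def test_empty_batch_rejected(self):
        params = init_params(ModelSpec(4), 0)
        with pytest.raises(ValueError):
            gradient(params, np.empty((0, 4)), np.empty(0, int))


class TestAdam:
    def test_zero_gradient_is_a_no_op(self):
        params = init_params(ModelSpec(4), 1)
        state = AdamState()
        zeros = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        new = adam_step(state, params, zeros, 0.1)
        assert new == params

    def test_first_step_moves_by_lr_times_sign(self, rng):
        params = init_params(ModelSpec(4), 1)
        grads = {k: rng.choice([-1.0, 1.0], size=v.shape) * 10
                 for k, v in params.arrays.items()}
        new = adam_step(AdamState(), params, grads, 0.05)
        for k in grads:
            step = new.arrays[k] - params.arrays[k]
            np.testing.assert_allclose(step, -0.05 * np.sign(grads[k]),
                                       rtol=1e-6)

    def test_identical_states_give_identical_results(self, rng):
        grads = {"W0": rng.normal(size=(4, 12))}
        p = init_params(ModelSpec(4), 1)
        a = adam_step(AdamState(), p, grads, 0.01)
        b = adam_step(AdamState(), p, grads, 0.01)
        assert a == b


class TestStandardizer:
    def test_two_point_column(self):
        s = fit_standardizer(np.array([[1.0], [3.0]]))
        assert s.location[0] == 2.0 and s.scale[0] == 1.0
        np.testing.assert_allclose(s.apply(np.array([[1.0], [3.0]])).ravel(),
                                   [-1.0, 1.0])

    def test_training_rows_become_centered(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 6))
        s = fit_standardizer(X)
        Z = s.apply(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_guard(self, caplog):
        with caplog.at_level("WARNING", logger="fedaffect"):
            s = fit_standardizer(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_array_equal(s.apply(np.full((3, 1), 5.0)), 0.0)
        assert "constant" in caplog.text


class TestEmbeddings:
    def test_augmentation_length_and_content(self):
        x = np.arange(32, dtype=float)
        e = np.array([9.0, -9.0])
        out = augment_with_embedding(x, e)
        assert out.shape == (34,)
        np.testing.assert_array_equal(out[-2:], e)

    def test_zero_width_embedding_is_identity(self):
        x = np.arange(5, dtype=float)
        np.testing.assert_array_equal(augment_with_embedding(x, np.empty(0)), x)

    def test_unknown_subject_raises(self):
        table = EmbeddingTable.init(["A"], dim=2, seed=0)
        with pytest.raises(KeyError, match="unseen"):
            table.get("B")

    def test_embedding_only_predictions_constant_within_user(self):
        # zero out the real features: predictions depend on the user alone
        table = EmbeddingTable.init(["A", "B"], dim=2, seed=1, scale=1.0)
        params = init_params(ModelSpec(4 + 2), 5)
        sids = np.array(["A"] * 4 + ["B"] * 4)
        X = augment_rows(np.zeros((8, 4)), sids, table)
        pred = predict(params, X)
        assert len(set(pred[:4])) == 1 and len(set(pred[4:])) == 1


class TestAccuracy:
    @pytest.mark.parametrize("pred,true,expected", [
        ([0, 1, 2], [0, 1, 2], 1.0),
        ([0, 0, 0], [1, 1, 1], 0.0),
        ([0, 1, 2, 2], [0, 1, 2, 1], 0.75),
    ])
    def test_fraction_of_matches(self, pred, true, expected):
        assert accuracy(pred, true) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            accuracy([0, 1], [0, 1, 2])


def test_train_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(beta1=1.0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
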