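import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import batch_from_arrays
from dtcn.network import (
    NetworkParams,
    TrainConfig,
    backprop_update,
    concatenate,
    equivalent_dbn_config,
    forward,
    gradient_route,
    load_model,
    majority_vote,
    param_count,
    pool_label_counts,
    save_model,
    sigmoid,
    train_network,
)
from dtcn.network import _gradients, _targets


class TestConcatenate:
    def test_worked_example_18_rows_ts3(self):
        out = concatenate(np.arange(36.0).reshape(18, 2), 3)
        assert out.shape == (16, 6)

    def test_ts1_is_identity(self):
        a = np.random.default_rng(0).normal(size=(7, 3))
        np.testing.assert_array_equal(concatenate(a, 1), a)

    def test_rows_joined_in_time_order(self):
        a = np.arange(10.0).reshape(5, 2)
        out = concatenate(a, 3)
        assert out.shape == (3, 6)
        np.testing.assert_array_equal(out[0], [0, 1, 2, 3, 4, 5])
        np.testing.assert_array_equal(out[2], [4, 5, 6, 7, 8, 9])

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError, match="too small"):
            concatenate(np.zeros((2, 3)), 3)


class TestPoolCounts:
    def test_direct_summation(self):
        out = pool_label_counts(np.array([[1, 0], [0, 1], [1, 0]]), 3)
        np.testing.assert_array_equal(out, [[2, 1]])

    def test_ts1_identity(self):
        c = np.array([[3, 1], [2, 2]])
        np.testing.assert_array_equal(pool_label_counts(c, 1), c)

    def test_row_sum_conservation(self):
        # constant per-row sum w multiplies by TS after pooling
        c = np.tile([[3, 2, 2]], (9, 1))
        for ts in (1, 2, 4):
            np.testing.assert_array_equal(
                pool_label_counts(c, ts).sum(axis=1), np.full(9 - ts + 1, 7 * ts)
            )


class TestMajorityVote:
    @pytest.mark.parametrize(
        "counts,expected", [([5, 2, 1], 0), ([0, 0, 7], 2)]
    )
    def test_strict_majority(self, counts, expected):
        assert majority_vote(np.array(counts), rng_seed=0) == expected

    def test_tie_broken_uniformly(self):
        picks = np.array(
            [majority_vote(np.array([3, 3]), rng_seed=s) for s in range(10_000)]
        )
        freq = picks.mean()
        assert 0.48 <= freq <= 0.52

    def test_deterministic_given_seed(self):
        assert majority_vote(np.array([2, 2, 1]), 7) == majority_vote(
            np.array([2, 2, 1]), 7
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            majority_vote(np.array([0, 0]), 0)


class TestForward:
    def test_surviving_rows_shrink_by_concatenations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(18, 224))
        counts = np.zeros((18, 2), dtype=int)
        counts[:, 0] = 16
        params = NetworkParams.initialize((224, 20, 20, 20, 2), ts=5, seed=0)
        state = forward(params, X, counts)
        assert state.output.shape == (18 - 3 * 4, 2)

    def test_softmax_rows_normalized(self, random_batch):
        params = NetworkParams.initialize((6, 5, 4, 2), ts=2, seed=1)
        state = forward(params, random_batch)
        np.testing.assert_allclose(state.output.sum(axis=1), 1.0, atol=1e-12)

    def test_counts_row_aligned_with_activations(self, random_batch):
        params = NetworkParams.initialize((6, 5, 4, 2), ts=2, seed=1)
        state = forward(params, random_batch)
        for ac, pc in zip(state.hidden_concat, state.pooled_counts):
            assert ac.shape[0] == pc.shape[0]
        assert state.output.shape[0] == state.final_counts.shape[0]

    def test_batch_too_small_names_minimum(self, random_batch):
        params = NetworkParams.initialize((6, 5, 5, 5, 2), ts=5, seed=0)
        with pytest.raises(ValueError, match=str(params.min_batch_size)):
            forward(params, random_batch)


class TestGradientRoute:
    def test_ts1_identity(self):
        t = np.random.default_rng(0).normal(size=(6, 4))
        np.testing.assert_array_equal(gradient_route(t, 1, 6), t)

    @given(
        seed=st.integers(0, 10_000),
        ts=st.integers(1, 4),
        H=st.integers(1, 5),
        extra=st.integers(0, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_delta_conservation(self, seed, ts, H, extra):
        # total routed delta equals total incoming delta
        pre_rows = ts + extra
        table = np.random.default_rng(seed).normal(size=(pre_rows - ts + 1, ts * H))
        routed = gradient_route(table, ts, pre_rows)
        assert routed.shape == (pre_rows, H)
        assert abs(routed.sum() - table.sum()) < 1e-12

    @given(
        seed=st.integers(0, 10_000),
        ts=st.integers(1, 4),
        H=st.integers(1, 5),
        extra=st.integers(0, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjoint_of_concatenation(self, seed, ts, H, extra):
        # <concatenate(A), G> == <A, route(G)> — the defining property
        pre_rows = ts + extra
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(pre_rows, H))
        G = rng.normal(size=(pre_rows - ts + 1, ts * H))
        lhs = float(np.sum(concatenate(A, ts) * G))
        rhs = float(np.sum(A * gradient_route(G, ts, pre_rows)))
        assert abs(lhs - rhs) < 1e-10

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            gradient_route(np.zeros((4, 6)), 2, 9)


def _finite_difference_max_rel_error(sizes, ts, B, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(B, sizes[0]))
    counts = rng.integers(0, 5, size=(B, sizes[-1]))
    counts[:, 0] += 1
    batch = batch_from_arrays(X, counts)
    params = NetworkParams.initialize(sizes, ts, seed)
    state = forward(params, batch)
    T = _targets(state, TrainConfig(seed=0), np.random.default_rng(0))
    grads_W, grads_b, _ = _gradients(params, state, T)

    def loss():
        out = forward(params, batch).output
        return float(-np.sum(T * np.log(np.clip(out, 1e-12, None))) / T.shape[0])

    eps, worst = 1e-5, 0.0
    for arrs, grads in ((params.weights, grads_W), (params.biases, grads_b)):
        for arr, g in zip(arrs, grads):
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                worst = max(
                    worst, abs(num - g[idx]) / max(1e-8, abs(num) + abs(g[idx]))
                )
    return worst


@pytest.mark.parametrize("ts", [1, 2, 3])
def test_analytic_gradients_match_central_differences(ts):
    assert _finite_difference_max_rel_error((6, 4, 3, 2), ts, B=8) < 1e-5


class TestReductionToPlainMLP:
    """At TS=1 the network is a plain sigmoid MLP, bit for bit."""

    @staticmethod
    def _mlp_forward(weights, biases, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(weights, biases)):
            y = h @ W + b
            if i == len(weights) - 1:
                z = np.exp(y - y.max(axis=1, keepdims=True))
                return acts, z / z.sum(axis=1, keepdims=True)
            h = sigmoid(y)
            acts.append(h)
        raise AssertionError

    @classmethod
    def _mlp_step(cls, weights, biases, X, T, lr):
        # textbook backprop for a sigmoid MLP with softmax cross-entropy
        acts, probs = cls._mlp_forward(weights, biases, X)
        R = probs.shape[0]
        delta = (probs - T) / R
        for i in range(len(weights) - 1, -1, -1):
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            if i > 0:
                a = acts[i]
                delta = (delta @ weights[i].T) * a * (1 - a)
            weights[i] -= lr * gW
            biases[i] -= lr * gb
        return weights, biases

    def test_forward_bit_identical(self, random_batch):
        params = NetworkParams.initialize((6, 5, 4, 2), ts=1, seed=3)
        state = forward(params, random_batch)
        _, probs = self._mlp_forward(params.weights, params.biases, random_batch.features)
        np.testing.assert_array_equal(state.output, probs)

    def test_one_update_bit_identical(self, random_batch):
        params = NetworkParams.initialize((6, 5, 4, 2), ts=1, seed=3)
        ref_W = [W.copy() for W in params.weights]
        ref_b = [b.copy() for b in params.biases]
        # tie-free counts: the voted one-hot target is deterministic
        T = np.zeros((10, 2))
        T[np.arange(10), random_batch.label_counts.argmax(axis=1)] = 1.0
        cfg = TrainConfig(learning_rate=0.1, seed=0)
        backprop_update(params, random_batch, cfg, rng=np.random.default_rng(0))
        self._mlp_step(ref_W, ref_b, random_batch.features, T, lr=0.1)
        for W1, W2 in zip(params.weights, ref_W):
            np.testing.assert_array_equal(W1, W2)
        for b1, b2 in zip(params.biases, ref_b):
            np.testing.assert_array_equal(b1, b2)


def test_single_small_step_does_not_increase_loss(random_batch):
    """One small-step update lowers the batch loss for ~all random inits."""
    ok = 0
    for s in range(100):
        params = NetworkParams.initialize((6, 4, 3, 2), ts=2, seed=s)
        cfg = TrainConfig(learning_rate=0.01, seed=s)
        state = forward(params, random_batch)
        T = _targets(state, cfg, np.random.default_rng(0))
        _, loss0 = backprop_update(params, random_batch, cfg, rng=np.random.default_rng(0))
        out = forward(params, random_batch).output
        loss1 = float(-np.sum(T * np.log(np.clip(out, 1e-12, None))) / T.shape[0])
        ok += loss1 <= loss0 + 1e-12
    assert ok >= 95


class TestComplexity:
    @pytest.mark.parametrize(
        "sizes,ts,expected",
        [
            ((224, 23, 23, 20, 2), 1, 6181),
            ((224, 31, 31, 20, 2), 1, 8565),
            ((224, 20, 20, 20, 2), 2, 6160),
        ],
    )
    def test_param_count(self, sizes, ts, expected):
        assert param_count(sizes, ts) == expected

    @pytest.mark.parametrize(
        "ts,expected", [(2, (23, 23, 20)), (5, (31, 31, 20))]
    )
    def test_equivalent_plain_network_widths(self, ts, expected):
        assert equivalent_dbn_config((224, 20, 20, 20, 2), ts) == expected

    def test_ts1_returns_input_widths(self):
        assert equivalent_dbn_config((224, 20, 20, 20, 2), 1) == (20, 20, 20)


def test_min_batch_enforced_for_training(random_batch):
    params = NetworkParams.initialize((6, 4, 3, 2), ts=2, seed=0)
    small = batch_from_arrays(
        random_batch.features[:5], random_batch.label_counts[:5]
    )
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError, match="minimum"):
        train_network(params, [small], cfg)
    # explicit override allows small batches
    cfg2 = TrainConfig(epochs=1, allow_small_batches=True)
    train_network(params, [small], cfg2)


def test_model_roundtrip(tmp_path, random_batch):
    params = NetworkParams.initialize((6, 4, 3, 2), ts=2, seed=9)
    path = tmp_path / "model.json"
    save_model(params, path)
    loaded = load_model(path)
    assert loaded.layer_sizes == params.layer_sizes
    assert loaded.ts == params.ts
    out1 = forward(params, random_batch).output
    out2 = forward(loaded, random_batch).output
    np.testing.assert_array_equal(out1, out2)
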