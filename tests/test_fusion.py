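"""Standardization, feature fusion, and the from-scratch MLP head."""

import numpy as np
import pytest

import oracles
from tumorlens import fusion
from tumorlens.fusion import (
    FusedFeatureVector,
    apply_standardizer,
    bce_loss,
    categorical_cross_entropy,
    classify,
    fit_standardizer,
    fuse,
    init_mlp,
    mlp_backward,
    mlp_forward,
    train_mlp,
    train_step,
)


class TestStandardizer:
    def test_population_std_formula(self):
        s = fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        out = apply_standardizer(s, np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_training_set_standardizes_to_zero_mean_unit_std(self, rng):
        X = rng.normal(3.0, 2.5, size=(40, 6))
        s = fit_standardizer(X)
        Z = apply_standardizer(s, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_feature_flagged_and_zeroed(self, rng):
        X = np.column_stack([rng.normal(size=10), np.full(10, 7.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            s = fit_standardizer(X)
        assert s.zero_variance.tolist() == [False, True]
        assert np.all(apply_standardizer(s, X)[:, 1] == 0.0)

    def test_leakage_guard_refuses_non_train_rows(self, rng):
        X = rng.normal(size=(6, 2))
        tags = ["train", "train", "val", "train", "test", "train"]
        with pytest.raises(ValueError, match="leakage"):
            fit_standardizer(X, split_tags=tags)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2"):
            fit_standardizer(np.ones((1, 3)))


class TestFuse:
    def test_fused_length_is_d1_plus_d2(self, rng):
        deep = rng.normal(size=49)
        hand = rng.normal(size=53)
        hand_names = [f"glcm_f{i}" for i in range(40)] + [f"shape_f{i}" for i in range(13)]
        fv = fuse(deep, hand, handcrafted_names=hand_names)
        assert fv.values.size == 102
        assert fv.provenance.count("deep") == 49
        assert fv.provenance.count("glcm") == 40
        assert fv.provenance.count("radiomics") == 13

    def test_empty_deep_part_is_ablation_identity(self, rng):
        hand = rng.normal(size=10)
        fv = fuse(np.array([]), hand)
        assert np.array_equal(fv.values, hand)

    def test_provenance_slicing_roundtrip(self, rng):
        deep = rng.normal(size=5)
        hand = rng.normal(size=4)
        fv = fuse(deep, hand, handcrafted_names=[f"glcm_{i}" for i in range(4)])
        assert np.array_equal(fv.part("deep"), deep)
        assert np.array_equal(fv.part("glcm"), hand)

    def test_ledger_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse(np.zeros(3), np.zeros(2), deep_names=["a"])


class TestForward:
    def test_zero_network_sigmoid_outputs_half(self):
        model = init_mlp([4, 1], out_activation="sigmoid", seed=0)
        model.weights[0][:] = 0.0
        pred, _ = mlp_forward(model, np.zeros(4))
        assert pred[0] == pytest.approx(0.5)

    def test_single_unit_hand_evaluation(self):
        model = init_mlp([1, 1], out_activation="sigmoid", seed=0)
        model.weights[0][:] = 2.0
        model.biases[0][:] = 1.0
        pred, _ = mlp_forward(model, np.array([0.5]))
        assert pred[0] == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-9)

    def test_softmax_rows_sum_to_one(self, rng):
        model = init_mlp([6, 5, 3], seed=2)
        pred, _ = mlp_forward(model, rng.normal(size=(7, 6)))
        assert np.allclose(pred.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_names_layer(self):
        model = init_mlp([4, 2], seed=0)
        with pytest.raises(ValueError, match="first-layer"):
            mlp_forward(model, np.zeros(5))


class TestLosses:
    def test_bce_worked_values(self):
        assert bce_loss([1.0], [1.0 - 1e-12]) == pytest.approx(0.0, abs=1e-9)
        assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2.0))
        assert bce_loss([0.0], [0.9]) == pytest.approx(-np.log(0.1))

    def test_bce_rejects_non_binary_labels(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [0.5])

    def test_categorical_rejects_non_onehot(self):
        with pytest.raises(ValueError):
            categorical_cross_entropy([[0.5, 0.5]], [[0.5, 0.5]])


class TestBackprop:
    @pytest.mark.parametrize("out_act,n_out", [("softmax", 3), ("sigmoid", 1)])
    def test_gradients_match_finite_differences(self, out_act, n_out):
        """Backprop agrees with central differences on every layer of a
        seeded 2-layer network, to relative 1e-5."""
        rng = np.random.default_rng(42)
        model = init_mlp([5, 4, n_out], out_activation=out_act, seed=1)
        X = rng.normal(size=(6, 5))
        if out_act == "softmax":
            y = np.eye(3)[rng.integers(0, 3, 6)]
            loss_fn = lambda: categorical_cross_entropy(y, mlp_forward(model, X)[0])
        else:
            y = rng.integers(0, 2, (6, 1)).astype(float)
            loss_fn = lambda: bce_loss(y, mlp_forward(model, X)[0])
        _, cache = mlp_forward(model, X)
        _, w_grads, b_grads = mlp_backward(model, cache, y)
        fd_w = oracles.finite_difference_grads(loss_fn, model.weights)
        fd_b = oracles.finite_difference_grads(loss_fn, model.biases)
        for got, want in zip(w_grads + b_grads, fd_w + fd_b):
            denom = np.maximum(np.abs(want) + np.abs(got), 1e-4)
            assert np.max(np.abs(got - want) / denom) < 1e-5

    def test_stale_cache_rejected(self):
        model = init_mlp([3, 2], seed=0)
        with pytest.raises(ValueError, match="cache"):
            mlp_backward(model, {}, np.zeros((1, 2)))

    def test_zero_learning_rate_leaves_model_unchanged(self, rng):
        model = init_mlp([4, 3, 2], seed=0, learning_rate=0.0)
        before = [W.copy() for W in model.weights]
        X = rng.normal(size=(5, 4))
        y = np.eye(2)[rng.integers(0, 2, 5)]
        train_step(model, X, y)
        for W0, W1 in zip(before, model.weights):
            assert np.array_equal(W0, W1)

    def test_one_step_descends_on_convex_logistic_problem(self, rng):
        model = init_mlp([3, 1], out_activation="sigmoid", seed=4, learning_rate=0.05)
        X = rng.normal(size=(20, 3))
        y = (X @ np.array([1.0, -2.0, 0.5]) > 0).astype(float).reshape(-1, 1)
        loss0 = train_step(model, X, y)
        pred, _ = mlp_forward(model, X)
        assert bce_loss(y, pred) < loss0


class TestTraining:
    def test_xor_is_learned(self):
        """Classic 2-2-1 separability check: XOR reaches 4/4."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        model = train_mlp(X, y, hidden_sizes=(2,), n_classes=1, epochs=5000,
                          batch_size=4, learning_rate=1.0, optimizer="gd",
                          hidden_activation="sigmoid", seed=1)
        pred, _ = mlp_forward(model, X)
        assert np.array_equal((pred.ravel() >= 0.5).astype(int), y)

    def test_same_seed_identical_final_weights(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30)
        kw = dict(hidden_sizes=(8,), epochs=20, seed=5)
        m1 = train_mlp(X, y, **kw)
        m2 = train_mlp(X, y, **kw)
        for a, b in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)
        assert m1.history == m2.history

    def test_history_length_equals_epochs(self, rng):
        X = rng.normal(size=(16, 3))
        y = rng.integers(0, 2, 16)
        model = train_mlp(X, y, hidden_sizes=(4,), epochs=7, seed=0)
        assert len(model.history) == 7


class TestClassify:
    def test_multiclass_argmax(self, rng):
        model = init_mlp([4, 4], seed=3)
        x = rng.normal(size=4)
        label, probs = classify(model, x)
        assert label == int(np.argmax(probs))
        assert probs.sum() == pytest.approx(1.0)

    def test_binary_tie_goes_to_positive_class(self):
        model = init_mlp([2, 1], out_activation="sigmoid", seed=0)
        model.weights[0][:] = 0.0
        model.biases[0][:] = 0.0
        label, probs = classify(model, np.zeros(2))
        assert label == 1
        assert probs[1] == pytest.approx(0.5)

    def test_accepts_fused_feature_vector(self, rng):
        model = init_mlp([6, 3], seed=1)
        fv = FusedFeatureVector(rng.normal(size=6), [f"f{i}" for i in range(6)],
                                ["deep"] * 6)
        label, probs = classify(model, fv)
        assert 0 <= label < 3


class TestPersistence:
    def test_model_json_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 2, 20)
        model = train_mlp(X, y, hidden_sizes=(4,), epochs=10, seed=2)
        std = fit_standardizer(X)
        path = tmp_path / "model.json"
        fusion.save_model(model, path, standardizer=std,
                          feature_names=[f"f{i}" for i in range(5)],
                          class_names=["neg", "pos"])
        loaded, std2, meta = fusion.load_model(path)
        for a, b in zip(model.weights, loaded.weights):
            assert np.allclose(a, b)
        assert np.allclose(std.means, std2.means)
        assert meta["class_names"] == ["neg", "pos"]
        p1, _ = mlp_forward(model, X)
        p2, _ = mlp_forward(loaded, X)
        assert np.allclose(p1, p2)
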