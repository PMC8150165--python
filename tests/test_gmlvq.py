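import dataclasses

import numpy as np
import pytest

from steroidstage.gmlvq import (
    GMLVQModel,
    TrainConfig,
    cost,
    cost_gradients,
    decision_score,
    decision_scores,
    init_model,
    model_from_json,
    model_to_json,
    predict,
    predict_batch,
    project_2d,
    relevances,
    squared_distance,
    train,
)
from steroidstage.preprocessing import FeatureMatrix

from oracles import naive_cost, naive_predict, naive_squared_distance

rng = np.random.default_rng(12345)


def blobs(n=50, d=5, sep=4.0, seed=0, sd=1.0, separable=False):
    """Two Gaussian classes separated by ``sep`` along feature 0.

    ``separable=True`` clips the separating feature so the realised samples
    are linearly separable with a margin (tail draws would otherwise overlap
    with small probability).
    """
    r = np.random.default_rng(seed)
    a = r.normal(0, sd, size=(n, d))
    b = r.normal(0, sd, size=(n, d))
    b[:, 0] += sep
    if separable:
        a[:, 0] = np.minimum(a[:, 0], sep / 2 - 0.5)
        b[:, 0] = np.maximum(b[:, 0], sep / 2 + 0.5)
    values = np.vstack([a, b])
    labels = ("neg",) * n + ("pos",) * n
    names = tuple(f"f{i}" for i in range(d))
    return FeatureMatrix(values=values, feature_names=names, labels=labels)


def manual_model(prototypes, labels, omega=None):
    prototypes = np.asarray(prototypes, dtype=float)
    d = prototypes.shape[1]
    if omega is None:
        omega = np.eye(d) / np.sqrt(d)
    return GMLVQModel(
        prototypes=prototypes,
        prototype_labels=tuple(labels),
        omega=np.asarray(omega, dtype=float),
        feature_names=tuple(f"f{i}" for i in range(d)),
    )


def random_instance(seed, n=8, d=4, classes=("a", "b")):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, d))
    y = tuple(classes[i % len(classes)] for i in range(n))
    fm = FeatureMatrix(values=X, feature_names=tuple(f"f{i}" for i in range(d)), labels=y)
    protos = r.normal(size=(len(classes), d))
    omega = r.normal(size=(d, d))
    omega /= np.sqrt(np.sum(omega**2))
    return fm, manual_model(protos, classes, omega)


class TestInit:
    def test_prototypes_start_at_class_means(self):
        fm = blobs(n=200, sep=2.0, seed=1)
        model = init_model(fm, seed=0)
        means = {
            c: fm.values[np.asarray(fm.labels) == c].mean(axis=0)
            for c in ("neg", "pos")
        }
        for w, lab in zip(model.prototypes, model.prototype_labels):
            assert np.all(np.abs(w - means[lab]) < 0.05)

    def test_initial_metric_is_scaled_identity_with_unit_trace(self):
        model = init_model(blobs(d=4), seed=0)
        np.testing.assert_allclose(model.lambda_matrix(), np.eye(4) / 4, atol=1e-15)
        assert np.trace(model.lambda_matrix()) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        fm = blobs()
        a = init_model(fm, seed=3)
        b = init_model(fm, seed=3)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)

    def test_undersized_class_rejected(self):
        fm = FeatureMatrix(
            values=np.zeros((3, 2)) + np.arange(3)[:, None],
            feature_names=("f0", "f1"),
            labels=("a", "a", "b"),
        )
        with pytest.raises(ValueError, match="'b'"):
            init_model(fm)


class TestDistances:
    def test_distance_to_own_prototype_is_zero(self):
        m = manual_model([[1.0, 2.0], [3.0, 4.0]], ["a", "b"])
        assert squared_distance(m, np.array([1.0, 2.0]))[0] == 0.0

    def test_identity_metric_unit_offset(self):
        d = 6
        m = manual_model([np.zeros(d)], ["a"])
        assert squared_distance(m, np.ones(d))[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_triple_loop(self, seed):
        fm, model = random_instance(seed, n=20, d=6)
        for x in fm.values:
            fast = squared_distance(model, x)
            slow = [
                naive_squared_distance(model.omega, w, x) for w in model.prototypes
            ]
            np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = manual_model([[0.0, 0.0]], ["a"])
        with pytest.raises(ValueError, match="length 2"):
            squared_distance(m, np.zeros(3))


class TestCost:
    def test_equidistant_sample_contributes_zero(self):
        m = manual_model([[-1.0], [1.0]], ["a", "b"], omega=[[1.0]])
        fm = FeatureMatrix(np.array([[0.0]]), ("f0",), ("a",))
        assert cost(m, fm) == pytest.approx(0.0)

    def test_sample_at_own_prototype_scores_minus_one(self):
        m = manual_model([[-1.0], [1.0]], ["a", "b"], omega=[[1.0]])
        fm = FeatureMatrix(np.array([[-1.0]]), ("f0",), ("a",))
        assert cost(m, fm) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_enumeration(self, seed):
        fm, model = random_instance(seed, n=6, d=4)
        assert cost(model, fm) == pytest.approx(
            naive_cost(model.prototypes, model.prototype_labels, model.omega,
                       fm.values, fm.labels),
            rel=1e-12,
        )

    def test_coincident_prototypes_give_zero_term(self):
        m = manual_model([[0.0], [0.0]], ["a", "b"], omega=[[1.0]])
        fm = FeatureMatrix(np.array([[0.0]]), ("f0",), ("a",))
        assert cost(m, fm) == 0.0


class TestTraining:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        fm = blobs(n=50, d=5, sep=4.0, seed=2, separable=True)
        model = train(init_model(fm, seed=0), fm, TrainConfig(epochs=100, seed=0))
        preds = predict_batch(model, fm.values)
        assert preds == list(fm.labels)

    def test_negligible_learning_rate_leaves_model_unchanged(self):
        fm = blobs(n=20, seed=3)
        m0 = init_model(fm, seed=0)
        m1 = train(m0, fm, TrainConfig(epochs=5, lr_prototype=1e-300))
        np.testing.assert_allclose(m1.prototypes, m0.prototypes, atol=1e-12)

    def test_batch_cost_is_non_increasing_with_step_halving(self):
        fm = blobs(n=40, d=6, sep=1.0, seed=4)
        model = train(init_model(fm, seed=1), fm, TrainConfig(epochs=60, lr_prototype=5.0))
        log = np.asarray(model.training_log)
        assert np.all(np.diff(log) <= 1e-12)

    def test_trace_stays_unit_through_training(self):
        fm = blobs(n=30, d=4, sep=2.0, seed=5)
        model = train(init_model(fm, seed=2), fm, TrainConfig(epochs=40))
        assert model.trace_log
        assert np.all(np.abs(np.asarray(model.trace_log) - 1.0) < 1e-10)

    def test_stochastic_mode_is_deterministic_given_seed(self):
        fm = blobs(n=20, d=3, sep=2.0, seed=6)
        cfg = TrainConfig(epochs=5, mode="stochastic", lr_prototype=0.05, seed=9)
        a = train(init_model(fm, seed=0), fm, cfg)
        b = train(init_model(fm, seed=0), fm, cfg)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)
        np.testing.assert_array_equal(a.omega, b.omega)

    def test_input_model_is_not_mutated(self):
        fm = blobs(n=20, seed=7)
        m0 = init_model(fm, seed=0)
        before = m0.prototypes.copy()
        train(m0, fm, TrainConfig(epochs=10))
        np.testing.assert_array_equal(m0.prototypes, before)
        assert not m0.trained


class TestGradients:
    def test_analytic_matches_finite_differences_on_one_instance(self):
        from oracles import finite_difference_gradients

        fm, model = random_instance(99, n=5, d=3)
        _, gw, go = cost_gradients(model, fm)

        def cost_fn(W, O):
            m = model.copy()
            m.prototypes, m.omega = W, O
            return cost(m, fm)

        fw, fo = finite_difference_gradients(cost_fn, model)
        denom = np.abs(fw) + np.abs(gw) + 1e-8
        assert np.max(np.abs(fw - gw) / denom) < 1e-4
        denom = np.abs(fo) + np.abs(go) + 1e-8
        assert np.max(np.abs(fo - go) / denom) < 1e-4


class TestPrediction:
    def test_prototype_point_maps_to_its_class(self):
        m = manual_model([[0.0, 0.0], [2.0, 2.0]], ["a", "b"])
        assert predict(m, np.array([0.0, 0.0])) == "a"
        assert predict(m, np.array([2.0, 2.0])) == "b"

    def test_symmetric_tie_resolves_to_first_sorted_label(self):
        m = manual_model([[-1.0], [1.0]], ["z_late", "a_early"], omega=[[1.0]])
        assert predict(m, np.array([0.0])) == "a_early"

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_scan(self, seed):
        fm, model = random_instance(seed + 50, n=20, d=5, classes=("a", "b", "c"))
        for x in fm.values:
            assert predict(model, x) == naive_predict(
                model.prototypes, model.prototype_labels, model.omega, x
            )


class TestDecisionScore:
    def setup_method(self):
        self.m = manual_model([[-1.0, 0.0], [1.0, 0.0]], ["neg", "pos"])

    def test_positive_prototype_scores_plus_one(self):
        assert decision_score(self.m, np.array([1.0, 0.0]), "pos") == pytest.approx(1.0)

    def test_equidistant_scores_zero(self):
        assert decision_score(self.m, np.array([0.0, 3.0]), "pos") == pytest.approx(0.0)

    def test_antisymmetric_under_arm_swap(self):
        X = rng.normal(size=(30, 2))
        s_pos = decision_scores(self.m, X, "pos")
        s_neg = decision_scores(self.m, X, "neg")
        np.testing.assert_allclose(s_pos, -s_neg, atol=1e-14)

    def test_thresholding_at_zero_reproduces_predict(self):
        X = rng.normal(size=(50, 2))
        s = decision_scores(self.m, X, "pos")
        preds = predict_batch(self.m, X)
        for score, p in zip(s, preds):
            assert (p == "pos") == (score > 0) or score == 0

    def test_requires_binary_model(self):
        m3 = manual_model([[0.0], [1.0], [2.0]], ["a", "b", "c"], omega=[[1.0]])
        with pytest.raises(ValueError, match="binary"):
            decision_score(m3, np.array([0.0]), "a")


class TestRelevances:
    def test_untrained_model_has_uniform_relevance(self):
        model = init_model(blobs(d=8), seed=0)
        rel = relevances(model)
        assert all(v == pytest.approx(1 / 8) for v in rel.values())
        assert sum(rel.values()) == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_feature_dominates_after_training(self):
        # classes differ only on feature 3 of 8
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 8))
            X[30:, 3] += 4.0
            fm = FeatureMatrix(X, tuple(f"f{i}" for i in range(8)),
                               ("neg",) * 30 + ("pos",) * 30)
            model = train(init_model(fm, seed=seed), fm,
                          TrainConfig(epochs=60, seed=seed))
            rel = relevances(model)
            if max(rel, key=rel.get) == "f3":
                wins += 1
        assert wins >= 18


class TestProjection:
    def test_rank_one_metric_zero_fills_second_coordinate(self):
        omega = np.zeros((3, 3))
        omega[0, 0] = 1.0
        m = manual_model([np.zeros(3), np.ones(3)], ["a", "b"], omega)
        with pytest.warns(UserWarning, match="rank"):
            coords = project_2d(m, rng.normal(size=(10, 3)))
        assert np.all(coords[:, 1] == 0.0)

    def test_projection_distance_bounded_by_metric_distance(self):
        fm, model = random_instance(7, n=15, d=5)
        coords = project_2d(model, fm.values)
        for i in range(5):
            for j in range(5):
                dp = np.sum((coords[i] - coords[j]) ** 2)
                dm = np.sum(((fm.values[i] - fm.values[j]) @ model.omega.T) ** 2)
                assert dp <= dm + 1e-10

    def test_equality_when_rank_at_most_two(self):
        r = np.random.default_rng(3)
        omega = np.outer(r.normal(size=3), [1.0, 0.0, 0.0]) + np.outer(
            r.normal(size=3), [0.0, 1.0, 0.0]
        )
        omega /= np.sqrt(np.sum(omega**2))
        m = manual_model([np.zeros(3), np.ones(3)], ["a", "b"], omega.T)
        X = r.normal(size=(8, 3))
        coords = project_2d(m, X)
        for i in range(8):
            for j in range(8):
                dp = np.sum((coords[i] - coords[j]) ** 2)
                dm = (X[i] - X[j]) @ m.lambda_matrix() @ (X[i] - X[j])
                assert dp == pytest.approx(dm, abs=1e-10)


class TestInvariances:
    def test_predictions_invariant_under_orthogonal_transform(self):
        fm, model = random_instance(21, n=20, d=4)
        q, _ = np.linalg.qr(np.random.default_rng(5).normal(size=(4, 4)))
        rotated = GMLVQModel(
            prototypes=model.prototypes @ q.T,
            prototype_labels=model.prototype_labels,
            omega=model.omega @ q.T,
            feature_names=model.feature_names,
        )
        for x in fm.values:
            assert predict(model, x) == predict(rotated, q @ x)


class TestSerialisation:
    def test_json_round_trip_reproduces_predictions_exactly(self, tmp_path):
        fm = blobs(n=30, d=4, sep=2.0, seed=8)
        model = train(init_model(fm, seed=1), fm, TrainConfig(epochs=30))
        path = tmp_path / "model.json"
        model_to_json(model, path)
        back = model_from_json(path)
        np.testing.assert_array_equal(back.prototypes, model.prototypes)
        np.testing.assert_array_equal(back.omega, model.omega)
        a = decision_scores(model, fm.values, "pos")
        b = decision_scores(back, fm.values, "pos")
        np.testing.assert_array_equal(a, b)
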