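"""Normalisation, SVM training, metrics against sweep oracles, nested
cross-validation behaviour, prediction, model serialisation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from svindel.classifier import (
    DEFAULT_C_GRID,
    LinearModel,
    NormalizationBounds,
    TrainingSet,
    apply_normalization,
    auc,
    fit_normalization,
    load_model,
    nested_cv,
    predict,
    save_model,
    select_c,
    spec_sens_bep,
    train_svm,
    weight_report,
)
from svindel.features import LabeledFeatureVector
from svindel.simdata import (
    make_planted_direction_set,
    make_shifted_training_set,
    permute_labels,
)

from ._oracles import auc_pairwise, bep_sweep


class TestNormalization:
    def test_affine_map_to_unit_interval(self):
        bounds = fit_normalization(np.array([[2.0], [4.0], [6.0]]))
        out = apply_normalization(np.array([[2.0], [4.0], [6.0]]), bounds)
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_unseen_values_clipped(self):
        bounds = NormalizationBounds(minimum=np.array([2.0]), maximum=np.array([6.0]))
        assert apply_normalization(np.array([[8.0]]), bounds)[0, 0] == 1.0
        assert apply_normalization(np.array([[0.0]]), bounds)[0, 0] == 0.0

    def test_constant_column_maps_to_zero(self):
        bounds = fit_normalization(np.array([[3.0], [3.0], [3.0]]))
        assert apply_normalization(np.array([[3.0]]), bounds)[0, 0] == 0.0


class TestTrainSvm:
    def test_separable_data_fits_perfectly(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.vstack(
            [rng.normal(0.2, 0.05, size=(n, 2)), rng.normal(0.8, 0.05, size=(n, 2))]
        )
        y = np.array([-1] * n + [1] * n)
        ts = TrainingSet(X=X, y=y, feature_names=["a", "b"], kind="deletion")
        model = train_svm(ts, C=10)
        vecs = [
            LabeledFeatureVector(f"v{k}", "deletion", ["a", "b"], X[k])
            for k in range(2 * n)
        ]
        calls = [cls for _, cls in predict(model, vecs)]
        assert calls == y.tolist()

    def test_hard_margin_matches_hand_solved_qp(self):
        # normalised points: negatives at x1=0, positives at x1=1 -> the
        # maximum-margin separator is w=(2, 0), b=-1
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        ts = TrainingSet(X=X, y=y, feature_names=["a", "b"], kind="deletion")
        model = train_svm(ts, C=1e6)
        np.testing.assert_allclose(model.weights, [2.0, 0.0], atol=1e-4)
        assert model.bias == pytest.approx(-1.0, abs=1e-4)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.ones(4, dtype=int)
        with pytest.raises(ValueError):
            TrainingSet(X=X, y=y, feature_names=["a", "b"]).y
            train_svm(TrainingSet(X=X, y=y, feature_names=["a", "b"]))


class TestMetrics:
    def test_perfect_and_inverted_ranking(self):
        labels = [1, 1, -1, -1]
        assert auc([4, 3, 2, 1], labels) == 1.0
        assert spec_sens_bep([4, 3, 2, 1], labels) == 1.0
        assert auc([1, 2, 3, 4], labels) == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])
        with pytest.raises(ValueError):
            spec_sens_bep([1, 2], [-1, -1])

    @pytest.mark.parametrize("seed", range(5))
    def test_agree_with_exhaustive_sweep_oracles(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.choice([-1, 1], size=n)
            if len(set(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                auc_pairwise(scores, labels), abs=1e-12
            )
            assert spec_sens_bep(scores, labels) == pytest.approx(
                bep_sweep(scores, labels), abs=1e-12
            )
            # third route: the stock ROC integrator
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score((labels + 1) // 2, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = rng.choice([-1, 1], size=50)
        transformed = np.exp(3 * scores)
        assert auc(scores, labels) == auc(transformed, labels)
        assert spec_sens_bep(scores, labels) == spec_sens_bep(transformed, labels)

    def test_random_scores_concentrate_at_half(self):
        rng = np.random.default_rng(4)
        aucs = [
            auc(rng.normal(size=200), np.array([1, -1] * 100)) for _ in range(100)
        ]
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1


class TestNestedCv:
    def test_informative_feature_detected_and_null_is_random(self):
        ts = make_shifted_training_set(n=200, n_features=5, shift=2.0, seed=1)
        report = nested_cv(ts, k=5, repeats=3, seed=1)
        assert report.mean_auc >= 0.85
        null = permute_labels(ts, seed=1)
        null_report = nested_cv(null, k=5, repeats=3, seed=1)
        assert 0.3 <= null_report.mean_auc <= 0.7

    def test_fixed_seed_reproduces_report(self):
        ts = make_shifted_training_set(n=80, n_features=3, seed=2)
        a = nested_cv(ts, k=4, repeats=2, seed=7)
        b = nested_cv(ts, k=4, repeats=2, seed=7)
        assert a.aucs == b.aucs and a.beps == b.beps and a.chosen_c == b.chosen_c

    def test_k_too_large_for_class_rejected(self):
        ts = make_shifted_training_set(n=12, n_features=2, seed=0)
        with pytest.raises(ValueError, match="smaller k"):
            nested_cv(ts, k=10, repeats=1, seed=0)

    def test_outer_test_points_cannot_leak_into_selection(self):
        """Perturbing outer-test rows must leave that fold's chosen C
        and normalisation bounds untouched."""
        ts = make_shifted_training_set(n=60, n_features=3, seed=3)
        base = nested_cv(ts, k=3, repeats=1, seed=5)
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(5)
        outer = StratifiedKFold(
            n_splits=3, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        (_, test0), *_ = outer.split(ts.X, ts.y)
        X2 = ts.X.copy()
        X2[test0] += 1000.0  # wreck the test rows only
        ts2 = TrainingSet(X=X2, y=ts.y.copy(), feature_names=ts.feature_names,
                          kind=ts.kind)
        perturbed = nested_cv(ts2, k=3, repeats=1, seed=5)
        assert perturbed.chosen_c[0][0] == base.chosen_c[0][0]
        np.testing.assert_array_equal(
            perturbed.fold_bounds[0][0].minimum, base.fold_bounds[0][0].minimum
        )
        np.testing.assert_array_equal(
            perturbed.fold_bounds[0][0].maximum, base.fold_bounds[0][0].maximum
        )


class TestPredictAndWeights:
    def _model(self):
        return LinearModel(
            weights=np.array([1.0, 0.0]),
            bias=-0.5,
            C=10.0,
            bounds=NormalizationBounds(
                minimum=np.array([0.0, 0.0]), maximum=np.array([1.0, 1.0])
            ),
            feature_names=["a", "b"],
            kind="deletion",
        )

    def test_decision_value_and_class(self):
        model = self._model()
        vec = LabeledFeatureVector("v", "deletion", ["a", "b"], [0.9, 0.1])
        [(value, cls)] = predict(model, [vec])
        assert value == pytest.approx(0.4)
        assert cls == 1

    def test_zero_decision_value_is_positive(self):
        model = self._model()
        vec = LabeledFeatureVector("v", "deletion", ["a", "b"], [0.5, 0.7])
        [(value, cls)] = predict(model, [vec])
        assert value == pytest.approx(0.0)
        assert cls == 1

    def test_feature_mismatch_rejected_with_names(self):
        model = self._model()
        vec = LabeledFeatureVector("v", "deletion", ["a", "c"], [0.5, 0.7])
        with pytest.raises(ValueError, match="'c'"):
            predict(model, [vec])

    def test_planted_direction_recovered(self):
        ts, w_true = make_planted_direction_set(n=500, n_features=8, seed=4)
        model = train_svm(ts, C=10)
        w = model.weights / np.linalg.norm(model.weights)
        assert float(w @ w_true) > 0.9
        # the planted informative direction has a positive first
        # component, so its learned weight must be positive too
        report = weight_report(model)
        weights = dict(report)
        assert weights["f0"] > 0
        assert [w for _, w in report] == sorted(
            (w for _, w in report), reverse=True
        )

    def test_model_file_roundtrip(self, tmp_path):
        ts = make_shifted_training_set(n=40, n_features=3, seed=6)
        model = train_svm(ts, C=0.1)
        model.seed = 6
        path = tmp_path / "model.txt"
        save_model(model, str(path))
        back = load_model(str(path))
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        assert back.C == model.C
        assert back.feature_names == model.feature_names
        assert back.kind == model.kind and back.seed == 6
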