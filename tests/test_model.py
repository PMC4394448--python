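import numpy as np
import pytest
from sklearn.metrics import roc_curve as sk_roc_curve

from protint import model as md
from protint.model import (
    ConfusionCounts,
    GridSpec,
    ModelConfig,
    compute_metrics,
    cross_validate,
    default_feature_ladder,
    grid_search,
    kernel_matrix,
    rbf_kernel,
    roc_auc,
    stratified_kfold,
    train,
)
from conftest import make_dataset, separable_blobs
from oracles import pairwise_auc


class TestRbfKernel:
    @pytest.mark.parametrize(
        "u,v,gamma,expected",
        [
            ((1.0, 2.0), (1.0, 2.0), 3.0, 1.0),
            ((1.0, 0.0), (0.0, 1.0), 0.5, np.exp(-1.0)),
        ],
    )
    def test_examples(self, u, v, gamma, expected):
        assert rbf_kernel(np.array(u), np.array(v), gamma) == pytest.approx(expected)

    def test_gamma_to_zero_limit(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        assert rbf_kernel(u, v, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)

    def test_unsquared_variant_uses_plain_distance(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert rbf_kernel(u, v, 0.5, squared=False) == pytest.approx(
            np.exp(-0.5 * np.sqrt(2.0))
        )

    def test_gram_matrix_is_symmetric_psd(self, rng):
        X = rng.normal(size=(15, 6))
        K = kernel_matrix(X, X, gamma=0.7)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10
        assert np.allclose(np.diag(K), 1.0)


class TestMetrics:
    @pytest.mark.parametrize(
        "c,sens,spec,acc",
        [
            (ConfusionCounts(TP=5, FP=0, TN=5, FN=0), 1.0, 1.0, 1.0),
            (ConfusionCounts(TP=64, FP=6, TN=62, FN=5), 64 / 69, 62 / 68, 126 / 137),
            (ConfusionCounts(TP=0, FP=0, TN=5, FN=5), 0.0, 1.0, 0.5),
        ],
    )
    def test_examples(self, c, sens, spec, acc):
        report = compute_metrics(c)
        assert report.sensitivity == pytest.approx(sens)
        assert report.specificity == pytest.approx(spec)
        assert report.accuracy == pytest.approx(acc)

    def test_empty_actual_class_is_hard_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(TP=0, FP=5, TN=5, FN=0))

    def test_accuracy_is_prevalence_weighted_mean_of_sens_spec(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            r = compute_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            P, N = tp + fn, tn + fp
            assert r.accuracy == pytest.approx(
                (r.sensitivity * P + r.specificity * N) / (P + N)
            )
            assert min(r.sensitivity, r.specificity) <= r.accuracy + 1e-12
            assert r.accuracy <= max(r.sensitivity, r.specificity) + 1e-12


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.4, 0.1], [1, 1, 0, 0], 1.0),
            ([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0], 0.75),
            ([0.5, 0.5], [1, 0], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_curve_spans_unit_square_monotonically(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        curve = roc_auc(scores, labels)
        pts = np.array(curve.points)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= -1e-12).all()
        assert (np.diff(pts[:, 1]) >= -1e-12).all()

    def test_matches_pairwise_statistic_and_sklearn(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = (rng.random(n) < 0.4).astype(int)
            labels[0], labels[1] = 1, 0
            curve = roc_auc(scores, labels)
            assert curve.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
            fpr, tpr, _ = sk_roc_curve(labels, scores, drop_intermediate=False)
            assert np.allclose(np.trapezoid(tpr, fpr), curve.auc)

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestStratifiedKFold:
    def test_137_samples_split_as_28_28_27_27_27(self):
        dataset = make_dataset(np.zeros((137, 2)), [1] * 69 + [0] * 68)
        folds = stratified_kfold(dataset, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [27, 27, 27, 28, 28]
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(137))

    def test_balanced_ten_samples_one_of_each_class_per_fold(self):
        dataset = make_dataset(np.zeros((10, 2)), [1] * 5 + [0] * 5)
        for fold in stratified_kfold(dataset, k=5, seed=3):
            assert len(fold) == 2
            assert sorted(dataset.y[fold]) == [0, 1]

    def test_same_seed_gives_identical_folds(self, toy_separable):
        a = stratified_kfold(toy_separable, k=5, seed=7)
        b = stratified_kfold(toy_separable, k=5, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_equal_n_is_leave_one_out(self):
        dataset = make_dataset(np.zeros((10, 2)), [1] * 5 + [0] * 5)
        folds = stratified_kfold(dataset, k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 1 for f in folds)

    def test_class_smaller_than_k_is_hard_error(self):
        dataset = make_dataset(np.zeros((8, 2)), [1] * 3 + [0] * 5)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(dataset, k=5, seed=0)

    def test_replicates_stay_in_one_fold(self):
        # 10 sources x3 replicates per class
        y, accs = [], []
        for cls, prefix in ((1, "P"), (0, "N")):
            for i in range(10):
                for rep in ("", ".rep2", ".rep3"):
                    accs.append(f"{prefix}{i}{rep}")
                    y.append(cls)
        dataset = make_dataset(np.zeros((60, 2)), y, accessions=accs)
        folds = stratified_kfold(dataset, k=5, seed=1)
        groups = np.asarray(dataset.groups)
        for fold in folds:
            in_fold = set(groups[fold])
            for g in in_fold:
                assert (groups == g).sum() == np.isin(groups[fold], [g]).sum()


class TestTrain:
    def test_separable_data_reaches_training_accuracy_one(self, toy_separable):
        model = train(toy_separable, ModelConfig(C=10, gamma=0.1), seed=0)
        assert (model.predict(toy_separable.X) == toy_separable.y).mean() == 1.0

    def test_single_class_is_hard_error(self):
        dataset = make_dataset(np.zeros((6, 2)), [1] * 6)
        with pytest.raises(ValueError):
            train(dataset, ModelConfig())

    def test_label_flip_flips_predictions(self, toy_separable):
        flipped = make_dataset(toy_separable.X, 1 - toy_separable.y,
                               accessions=toy_separable.accessions)
        m1 = train(toy_separable, ModelConfig(C=5, gamma=0.2), seed=0, probability=False)
        m2 = train(flipped, ModelConfig(C=5, gamma=0.2), seed=0, probability=False)
        assert np.array_equal(m1.predict(toy_separable.X), 1 - m2.predict(toy_separable.X))

    def test_exact_duplication_keeps_decision_boundary_when_separable(self, toy_separable):
        dup = make_dataset(
            np.vstack([toy_separable.X, toy_separable.X]),
            np.concatenate([toy_separable.y, toy_separable.y]),
            accessions=toy_separable.accessions
            + [a + ".rep2" for a in toy_separable.accessions],
        )
        config = ModelConfig(C=10, gamma=0.1)
        m1 = train(toy_separable, config, seed=0, probability=False)
        m2 = train(dup, config, seed=0, probability=False)
        assert np.allclose(
            m1.decision_values(toy_separable.X),
            m2.decision_values(toy_separable.X),
            atol=1e-4,
        )

    def test_feature_subset_is_stored_and_applied(self, strong_small):
        dataset, result = strong_small
        model = train(dataset, ModelConfig(C=2, gamma=0.5, n_features=10), seed=0)
        assert len(model.selected_indices) == 10
        probs = model.score_records(list(result.proteome)[:3])
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_probabilities_deterministic_for_fixed_seed(self, toy_separable):
        p1 = train(toy_separable, ModelConfig(), seed=4).positive_probability(toy_separable.X)
        p2 = train(toy_separable, ModelConfig(), seed=4).positive_probability(toy_separable.X)
        assert np.array_equal(p1, p2)


class TestCrossValidate:
    def test_separable_data_scores_high(self, toy_separable):
        cv = cross_validate(toy_separable, ModelConfig(C=10, gamma=0.1), k=5, seed=0)
        assert cv.metrics.accuracy >= 0.95
        assert cv.metrics.confusion.total == len(toy_separable)

    def test_permuted_labels_are_at_chance(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.array([1] * 50 + [0] * 50)
        rng.shuffle(y)
        cv = cross_validate(make_dataset(X, y), ModelConfig(C=2, gamma=0.5), k=5, seed=0)
        assert 0.35 <= cv.metrics.accuracy <= 0.65

    def test_leave_one_out_pools_n_single_sample_folds(self):
        dataset = separable_blobs(n_per_class=5, seed=2)
        cv = cross_validate(dataset, ModelConfig(C=10, gamma=0.1), k=10, seed=0)
        assert cv.metrics.confusion.total == 10

    def test_bit_reproducible_for_fixed_seed(self, strong_small):
        dataset, _ = strong_small
        config = ModelConfig(C=2, gamma=0.5, n_features=20)
        a = cross_validate(dataset, config, seed=5)
        b = cross_validate(dataset, config, seed=5)
        assert np.array_equal(a.scores, b.scores)
        assert a.metrics == b.metrics


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, toy_separable):
        grid = GridSpec(C_values=(3.0,), gamma_values=(0.2,),
                        feature_count_candidates=(0,))
        result = grid_search(toy_separable, grid, seed=0)
        assert result.best_config == ModelConfig(C=3.0, gamma=0.2, n_features=0)
        assert len(result.surface) == 1

    def test_default_ladders_give_189_cells_per_feature_count(self, toy_separable):
        grid = GridSpec(feature_count_candidates=(0,))
        result = grid_search(toy_separable, grid, seed=0)
        assert len(result.surface) == 9 * 21

    def test_tie_resolves_to_fewer_features_then_smaller_c_then_gamma(self, toy_separable):
        # perfectly separable: every cell reaches accuracy 1.0
        grid = GridSpec(C_values=(2.0, 1.0), gamma_values=(0.5, 0.25),
                        feature_count_candidates=(4, 2))
        result = grid_search(toy_separable, grid, seed=0)
        assert result.surface["accuracy"].max() == 1.0
        assert (result.surface["accuracy"] == 1.0).sum() > 1
        assert result.best_config == ModelConfig(C=1.0, gamma=0.25, n_features=2)

    def test_feature_ladder_halves_down_to_16(self):
        assert default_feature_ladder(60) == (60, 30, 16)
        assert default_feature_ladder(64) == (64, 32, 16)
        assert default_feature_ladder(433) == (433, 216, 108, 54, 27, 16)
        assert default_feature_ladder(16) == (16,)
        assert default_feature_ladder(10) == (10,)

    def test_recovers_planted_domains_at_optimum(self, strong_small):
        dataset, result = strong_small
        grid = GridSpec(C_values=(2.0,), gamma_values=(0.5,),
                        feature_count_candidates=(20,))
        gs = grid_search(dataset, grid, seed=0)
        model = train(dataset, gs.best_config, seed=0, probability=False)
        planted = set(dataset.space.domain_feature_indices(result.enriched_domains))
        recovered = planted & set(model.selected_indices.tolist())
        assert len(recovered) >= 0.8 * len(planted)
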