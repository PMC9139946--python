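"""Cross-validation, confusion metrics, ROC/AUC, and the full pipeline."""

import numpy as np
import pytest

from oracles import pair_count_auc

from pdcsp.csp import fit_csp
from pdcsp.evaluate import (
    ClassifierSpec,
    ConfusionCounts,
    confusion_metrics,
    evaluate_segments,
    kfold_indices,
    make_classifier,
    positive_scores,
    roc_auc,
    run_pipeline,
    train_classifier,
)
from pdcsp.features import FeatureConfig
from pdcsp.preprocess import BandSpec, preprocess


class TestKFold:
    def test_balanced_stratification(self):
        labels = np.array(["A", "B"] * 50)
        folds = kfold_indices(100, 10, labels, seed=0)
        assert len(folds) == 10
        for _, test_idx in folds:
            assert len(test_idx) == 10
            assert np.sum(labels[test_idx] == "A") == 5

    def test_union_and_disjointness(self):
        labels = np.array(["A", "B"] * 50)
        folds = kfold_indices(100, 10, labels, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(100))
        for train_idx, test_idx in folds:
            assert not set(train_idx) & set(test_idx)

    def test_seed_determinism(self):
        labels = np.array(["A", "B"] * 20)
        f1 = kfold_indices(40, 5, labels, seed=3)
        f2 = kfold_indices(40, 5, labels, seed=3)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            np.testing.assert_array_equal(te1, te2)
            np.testing.assert_array_equal(tr1, tr2)

    def test_tiny_class_falls_back_with_warning(self):
        labels = np.array(["A"] * 37 + ["B"] * 3)
        with pytest.warns(UserWarning, match="smallest class"):
            folds = kfold_indices(40, 10, labels, seed=0)
        assert len(folds) == 10

    def test_subject_blocking_keeps_groups_whole(self):
        labels = np.array(["A", "B"] * 30)
        groups = np.repeat([f"s{i}" for i in range(10)], 6)
        folds = kfold_indices(60, 5, labels, seed=0, groups=groups)
        for train_idx, test_idx in folds:
            assert not set(groups[train_idx]) & set(groups[test_idx])

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kfold_indices(10, 1, ["A"] * 10)
        with pytest.raises(ValueError):
            kfold_indices(5, 10, ["A"] * 5)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(TP=90, FN=10, TN=80, FP=20))
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["precision"] == pytest.approx(81.818, abs=1e-3)
        assert m["f_score"] == pytest.approx(85.714, abs=1e-3)
        assert m["undefined"] == []

    def test_perfect_classification(self):
        m = confusion_metrics(ConfusionCounts(TP=5, FN=0, TN=7, FP=0))
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f_score"):
            assert m[name] == pytest.approx(100.0)

    def test_symmetric_errors_give_half_accuracy(self):
        m = confusion_metrics(ConfusionCounts(TP=10, FN=10, TN=4, FP=4))
        assert m["accuracy"] == pytest.approx(50.0)

    def test_zero_denominator_flagged_not_zeroed(self):
        m = confusion_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=0))
        assert np.isnan(m["sensitivity"])
        assert "sensitivity" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["P", "P", "N", "N"]
        _, auc = roc_auc(scores, labels, positive="P")
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_chance(self):
        _, auc = roc_auc([0.5] * 6, ["P", "N"] * 3, positive="P")
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 40)
            labels = rng.choice(["P", "N"], size=n)
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            _, auc = roc_auc(scores, labels, positive="P")
            assert auc == pytest.approx(pair_count_auc(scores, labels, "P"), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], ["P", "P"], positive="P")


@pytest.fixture(scope="module")
def clusters():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0.0, 1.0, (40, 3)), rng.normal(10.0, 1.0, (40, 3))])
    y = np.array(["HC"] * 40 + ["PD_OFF"] * 40)
    return X, y


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["RF", "LDA", "QDA", "SVM", "KNN"])
    def test_separable_clusters_trained_perfectly(self, clusters, kind):
        X, y = clusters
        clf = train_classifier(ClassifierSpec(kind=kind, seed=0), X, y)
        assert np.mean(clf.predict(X) == y) == 1.0
        scores = positive_scores(clf, X, "PD_OFF")
        assert scores[y == "PD_OFF"].min() > scores[y == "HC"].max()

    def test_knn_score_is_neighbor_fraction(self, clusters):
        X, y = clusters
        clf = train_classifier(ClassifierSpec(kind="KNN", knn_k=3), X, y)
        scores = positive_scores(clf, X, "PD_OFF")
        # vote fractions are multiples of 1/kn
        np.testing.assert_allclose(scores * 3, np.round(scores * 3), atol=1e-12)

    def test_even_knn_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ClassifierSpec(kind="KNN", knn_k=4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec(kind="MLP")

    def test_shuffled_labels_give_chance_level(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 4))
        y = rng.permutation(np.array(["HC", "PD_OFF"] * 150))
        from sklearn.model_selection import cross_val_score
        acc = cross_val_score(make_classifier(ClassifierSpec(kind="KNN")), X, y,
                              cv=10).mean()
        assert 0.40 <= acc <= 0.60


class TestPipeline:
    def test_separable_dataset_high_accuracy(self, separable_dataset):
        result = run_pipeline(separable_dataset,
                              feature_config=FeatureConfig(metric="VAR"), seed=0)
        assert result.mean("accuracy") >= 95.0
        assert 0.0 <= result.mean("auc") <= 1.0
        for name in ("accuracy", "sensitivity", "specificity"):
            assert 0.0 <= result.mean(name) <= 100.0

    def test_seed_determinism(self, small_dataset):
        kwargs = dict(feature_config=FeatureConfig(metric="LOGEN"), seed=5)
        r1 = run_pipeline(small_dataset, **kwargs)
        r2 = run_pipeline(small_dataset, **kwargs)
        assert r1.summary() == r2.summary()
        for f1, f2 in zip(r1.per_fold, r2.per_fold):
            assert f1.counts == f2.counts

    def test_fold_metrics_recompute_from_counts(self, small_dataset):
        result = run_pipeline(small_dataset, seed=0)
        for fold in result.per_fold:
            again = confusion_metrics(fold.counts)
            for name in ("accuracy", "sensitivity", "specificity", "precision"):
                assert fold.metrics[name] == again[name]

    def test_fold_mean_accuracy_matches_pooled_count(self, small_dataset):
        result = run_pipeline(small_dataset, seed=0)
        sizes = {f.counts.total for f in result.per_fold}
        if len(sizes) == 1:  # equal folds: fold-mean equals pooled accuracy
            pooled = 100.0 * sum(f.counts.TP + f.counts.TN for f in result.per_fold) \
                / sum(f.counts.total for f in result.per_fold)
            assert result.mean("accuracy") == pytest.approx(pooled)

    def test_positive_class_is_patient_group(self, small_dataset):
        result = run_pipeline(small_dataset, seed=0)
        assert result.positive == "PD_OFF"

    def test_json_and_roc_export(self, small_dataset, tmp_path):
        result = run_pipeline(small_dataset, seed=0)
        result.to_json(tmp_path / "eval.json")
        result.roc_to_csv(tmp_path / "roc.csv")
        import json
        payload = json.loads((tmp_path / "eval.json").read_text())
        assert set(payload) == {"positive", "config", "summary", "folds"}
        assert len(payload["folds"]) == 10
        import pandas as pd
        roc = pd.read_csv(tmp_path / "roc.csv")
        assert list(roc.columns) == ["fold", "fpr", "tpr"]

    def test_subject_mode_blocks_subjects(self, separable_dataset):
        segset = preprocess(separable_dataset, BandSpec(), 2.0)
        result = evaluate_segments(segset, k=4, seed=0, cv_mode="subject")
        assert len(result.per_fold) == 4


class TestLeakageGuard:
    """The CSP projection must be fit on training folds only."""

    def test_sentinel_in_test_fold_leaves_projection_unchanged(self, small_dataset):
        segset = preprocess(small_dataset, BandSpec(), 2.0)
        base = evaluate_segments(segset, k=5, seed=0)
        folds = kfold_indices(segset.M, 5, segset.labels, seed=0)
        # corrupt fold 0's test segments with a huge sentinel; a leaking fit
        # would see it and change the projection
        corrupted = segset.segments.copy()
        rng = np.random.default_rng(99)
        corrupted[folds[0][1]] = 1e6 * rng.standard_normal(
            corrupted[folds[0][1]].shape)
        from pdcsp.preprocess import SegmentSet
        seg2 = SegmentSet(corrupted, segset.labels, T=segset.T, fs=segset.fs,
                          subject_ids=segset.subject_ids)
        corrupted_result = evaluate_segments(seg2, k=5, seed=0)
        np.testing.assert_array_equal(base.per_fold[0].csp_model.W_full,
                                      corrupted_result.per_fold[0].csp_model.W_full)

    def test_fold_model_equals_train_only_fit(self, small_dataset):
        segset = preprocess(small_dataset, BandSpec(), 2.0)
        result = evaluate_segments(segset, k=5, seed=0)
        folds = kfold_indices(segset.M, 5, segset.labels, seed=0)
        train_idx = folds[0][0]
        direct = fit_csp(segset.segments[train_idx], segset.labels[train_idx],
                         "PD_OFF", "HC")
        np.testing.assert_array_equal(result.per_fold[0].csp_model.W_full,
                                      direct.W_full)
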