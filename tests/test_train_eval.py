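import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, f1_score, matthews_corrcoef,
                             precision_score, recall_score)

from aeinit import (AEConfig, AssemblySpec, TrainConfig, assemble,
                    compute_metrics, cross_validate, evaluate_model,
                    holdout_evaluate, holdout_split, stratified_folds,
                    summarize, train_classifier)


def _probs_from_confusion(tp, tn, fp, fn, rng=None):
    """Labels and probabilities realizing a given confusion matrix at 0.5."""
    rng = rng or np.random.default_rng(0)
    y = np.array([1] * tp + [1] * fn + [0] * tn + [0] * fp)
    p = np.concatenate([rng.uniform(0.5, 1.0, tp), rng.uniform(0.0, 0.5, fn),
                        rng.uniform(0.0, 0.5, tn), rng.uniform(0.5, 1.0, fp)])
    return y, p


class TestStratifiedFolds:
    def test_exact_divisibility_gives_equal_folds(self):
        labels = np.array([1] * 40 + [0] * 60)
        folds = stratified_folds(labels, 10, seed=0)
        for f in folds:
            assert labels[f].sum() == 4 and len(f) == 10

    def test_pigeonhole_bound_on_uneven_positives(self):
        labels = np.array([1] * 43 + [0] * 57)
        folds = stratified_folds(labels, 10, seed=1)
        pos_counts = {int(labels[f].sum()) for f in folds}
        assert pos_counts <= {4, 5}

    def test_folds_partition_all_indices(self):
        labels = np.array([0, 1] * 25)
        folds = stratified_folds(labels, 5, seed=2)
        joined = np.concatenate(folds)
        assert sorted(joined.tolist()) == list(range(50))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="class"):
            stratified_folds(np.array([1] * 3 + [0] * 50), 10, seed=0)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        r = compute_metrics(y, y.astype(float))
        assert (r.accuracy, r.f1, r.mcc, r.auc) == (100.0, 100.0, 1.0, 1.0)

    def test_symmetric_confusion_gives_zero_mcc(self):
        y, p = _probs_from_confusion(1, 1, 1, 1)
        assert compute_metrics(y, p).mcc == 0.0

    def test_frozen_oracle_confusion_90_10_80_20(self):
        # oracle: direct formula evaluation on TP=90 FN=10 TN=80 FP=20
        y, p = _probs_from_confusion(90, 80, 20, 10)
        r = compute_metrics(y, p)
        assert r.precision == pytest.approx(100 * 90 / 110, abs=1e-9)
        assert r.recall == pytest.approx(90.0, abs=1e-9)
        assert r.f1 == pytest.approx(100 * 2 * (90 / 110) * 0.9 / (90 / 110 + 0.9),
                                     abs=1e-9)
        assert r.mcc == pytest.approx(
            (90 * 80 - 20 * 10) / np.sqrt(110 * 100 * 100 * 90), abs=1e-12)
        assert r.mcc == pytest.approx(0.7035264707, abs=1e-9)
        assert r.accuracy == pytest.approx(85.0, abs=1e-9)

    def test_agrees_with_sklearn_on_random_confusions(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y, p = _probs_from_confusion(tp, tn, fp, fn, rng)
            r = compute_metrics(y, p)
            pred = (p >= 0.5).astype(int)
            assert r.accuracy == pytest.approx(100 * accuracy_score(y, pred), abs=1e-9)
            assert r.precision == pytest.approx(
                100 * precision_score(y, pred, zero_division=0), abs=1e-9)
            assert r.recall == pytest.approx(
                100 * recall_score(y, pred, zero_division=0), abs=1e-9)
            assert r.f1 == pytest.approx(
                100 * f1_score(y, pred, zero_division=0), abs=1e-9)
            assert r.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-9)

    def test_zero_denominators_yield_zero_not_errors(self):
        # all-negative predictions: no predicted positives
        r = compute_metrics(np.array([0, 0, 1]), np.array([0.1, 0.2, 0.3]))
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)
        assert r.mcc == 0.0
        # one-class truth: MCC denominator zero
        r = compute_metrics(np.array([1, 1]), np.array([0.9, 0.1]))
        assert r.mcc == 0.0

    def test_roc_sweep_monotone_and_anchored(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        p = rng.uniform(size=50)
        r = compute_metrics(y, p)
        fpr = [pt[0] for pt in r.roc_points]
        tpr = [pt[1] for pt in r.roc_points]
        assert r.roc_points[0] == (0.0, 0.0) and r.roc_points[-1] == (1.0, 1.0)
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))
        assert 0.0 <= r.auc <= 1.0

    def test_auc_of_perfect_and_inverted_rankings(self):
        y = np.array([0, 0, 1, 1])
        assert compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9])).auc == 1.0
        assert compute_metrics(y, np.array([0.9, 0.8, 0.2, 0.1])).auc == 0.0

    def test_empty_and_malformed_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([], [])
        with pytest.raises(ValueError, match="lengths"):
            compute_metrics([0, 1], [0.5])
        with pytest.raises(ValueError, match="probabilities"):
            compute_metrics([0, 1], [0.5, 1.5])


def _tiny_cfg(**kw):
    base = dict(epochs=15, batch_size=40, folds=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


def _ae_cfg(m, latent=8, epochs=15):
    return AEConfig(kind="basic", input_dim=m.n_features,
                    encoder_layer_sizes=[latent], epochs=epochs, batch_size=40)


class TestTrainClassifier:
    def test_epochs_zero_returns_initial_model_evaluation(self, small_labeled):
        m = small_labeled
        model = assemble(None, AssemblySpec(strategy="none"), input_dim=m.n_features)
        X, y = m.values, m.labels.to_numpy()
        initial = evaluate_model(model, X, y)
        fr = train_classifier(model, (X, y), (X, y), _tiny_cfg(epochs=0))
        assert fr.report.scalars() == initial.scalars()
        assert fr.best_epoch == 0

    def test_separable_data_reaches_high_f1(self, small_labeled):
        m = small_labeled
        model = assemble(None, AssemblySpec(strategy="none"), input_dim=m.n_features)
        X, y = m.values, m.labels.to_numpy()
        fr = train_classifier(model, (X, y), (X, y), _tiny_cfg(epochs=60))
        assert fr.report.f1 > 95

    def test_best_epoch_tracks_maximum_validation_f1(self, small_labeled):
        m = small_labeled
        model = assemble(None, AssemblySpec(strategy="none"), input_dim=m.n_features)
        X, y = m.values, m.labels.to_numpy()
        fr = train_classifier(model, (X, y), (X, y), _tiny_cfg(epochs=25))
        f1s = [h["f1"] for h in fr.history]
        assert f1s[fr.best_epoch] == max(f1s)
        assert fr.best_epoch == int(np.argmax(f1s))  # earliest on ties

    def test_single_class_fold_rejected(self):
        model = assemble(None, AssemblySpec(strategy="none"), input_dim=4)
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(model, (X, np.ones(10)), None, _tiny_cfg())


class TestCrossValidate:
    def test_two_fold_smoke_and_summary_mean(self, small_labeled):
        m = small_labeled
        results, summary = cross_validate(m, _ae_cfg(m), AssemblySpec(), _tiny_cfg())
        assert len(results) == 2
        fold_f1 = [fr.report.f1 for fr in results]
        assert summary["f1"]["mean"] == pytest.approx(np.mean(fold_f1))
        assert summary["f1"]["sd"] == pytest.approx(np.std(fold_f1, ddof=1))

    def test_identical_seeds_reproduce_summaries_exactly(self, small_labeled):
        m = small_labeled
        out = [cross_validate(m, _ae_cfg(m), AssemblySpec(), _tiny_cfg(seed=3))[1]
               for _ in range(2)]
        assert out[0] == out[1]

    def test_summarize_matches_fold_reports(self, small_labeled):
        m = small_labeled
        results, summary = cross_validate(
            m, _ae_cfg(m), AssemblySpec(strategy="none"), _tiny_cfg())
        assert summary == summarize(results)


class TestHoldout:
    def test_split_sizes_match_the_one_third_protocol(self):
        # 569 samples (60/40 classes) -> 381 train / 188 test
        y = np.array([0] * 357 + [1] * 212)
        tr, te = holdout_split(y, 0.33, seed=0)
        assert (len(tr), len(te)) == (381, 188)
        # 5906 samples (60/40) -> 3957 train / 1949 test
        y2 = np.array([0] * 3544 + [1] * 2362)
        tr2, te2 = holdout_split(y2, 0.33, seed=0)
        assert (len(tr2), len(te2)) == (3957, 1949)

    def test_split_is_stratified_within_one_sample(self):
        y = np.array([0] * 357 + [1] * 212)
        tr, te = holdout_split(y, 0.33, seed=5)
        global_rate = y.mean()
        assert abs(y[tr].sum() - global_rate * len(tr)) <= 1
        assert abs(y[te].sum() - global_rate * len(te)) <= 1

    def test_holdout_workflow_end_to_end(self, small_labeled):
        m = small_labeled
        res = holdout_evaluate(m, _ae_cfg(m), AssemblySpec(), _tiny_cfg())
        assert res["n_train"] + res["n_test"] == m.n_samples
        assert set(res["train_summary"]) >= {"f1", "mcc", "auc"}
        assert 0 <= res["test_report"].accuracy <= 100
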