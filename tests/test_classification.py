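import itertools

import numpy as np
import pytest

from divprop.classification import (
    MetricReport,
    TrainingConfig,
    confusion_by_diversity,
    cost_function,
    cross_val_performance,
    evaluate,
    train_classifier,
)


def pair_counting_auc(y, scores):
    """Exhaustive Mann-Whitney estimate: P(score_case > score_control)."""
    wins = ties = total = 0
    for i, j in itertools.product(np.where(y == 1)[0], np.where(y == 0)[0]):
        total += 1
        if scores[i] > scores[j]:
            wins += 1
        elif scores[i] == scores[j]:
            ties += 1
    return (wins + 0.5 * ties) / total


def test_linearly_separable_data_reaches_perfect_training_auc(rng):
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.1, n), rng.normal(0, 1, n)])
    for lam in (1e-3, 1.0, 1e3):
        fit = train_classifier(X, y, TrainingConfig(lambda_grid=(lam,)))
        report = evaluate(fit, X, y)
        assert report.auc == pytest.approx(1.0)


def test_shuffled_labels_stay_at_chance(rng):
    X = rng.normal(size=(200, 50))
    y = rng.permutation(np.repeat([0, 1], 100))
    perf = cross_val_performance(X, y, TrainingConfig(seed=3))
    assert 0.35 <= perf["auc"] <= 0.65


def test_predicted_probabilities_follow_sigmoid_arithmetic():
    fit_weights = np.array([2.0])
    intercept = -1.0
    from divprop.classification import FitResult

    fit = FitResult(fit_weights, intercept, 1.0, np.zeros(1), np.ones(1))
    X = np.array([[0.0], [0.5], [1.0], [-1.0]])
    expected = 1.0 / (1.0 + np.exp(-(X[:, 0] * 2.0 - 1.0)))
    assert np.allclose(fit.predict_proba(X), expected)


def test_evaluation_rows_never_touch_the_fit(rng):
    X = rng.normal(size=(80, 10))
    y = rng.integers(0, 2, 80)
    y[:5], y[-5:] = 0, 1
    fit1 = train_classifier(X[:60], y[:60], TrainingConfig(seed=0))
    _ = evaluate(fit1, X[60:], y[60:])
    X2 = X.copy()
    X2[60:] += rng.normal(0, 10, size=(20, 10))  # perturb only test rows
    fit2 = train_classifier(X2[:60], y[:60], TrainingConfig(seed=0))
    assert np.array_equal(fit1.weights, fit2.weights)
    assert fit1.lam == fit2.lam


def test_weight_norm_shrinks_with_stronger_regularization(rng):
    X = rng.normal(size=(100, 20))
    y = (X[:, 0] + rng.normal(0, 1, 100) > 0).astype(int)
    norms = [
        np.linalg.norm(train_classifier(X, y, TrainingConfig(lambda_grid=(lam,))).weights)
        for lam in (1e-3, 1e-1, 1e1, 1e3)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_cost_at_optimum_beats_zero_vector(rng):
    X = rng.normal(size=(50, 5))
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    lam = 1.0
    fit = train_classifier(X, y, TrainingConfig(lambda_grid=(lam,)))
    Xz = fit.transform(X)
    j_fit = cost_function(fit.weights, fit.intercept, Xz, y, lam)
    j_zero = cost_function(np.zeros(5), 0.0, Xz, y, lam)
    assert j_fit <= j_zero


def test_auc_equals_pair_counting_on_small_inputs(rng):
    for _ in range(5):
        n = int(rng.integers(8, 30))
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        scores = rng.random(n).round(1)  # coarse grid forces ties
        from divprop.classification import FitResult

        fit = FitResult(np.array([1.0]), 0.0, 1.0, np.zeros(1), np.ones(1))
        # feed scores through the logit so predict_proba returns them
        X = np.log(scores / (1 - scores + 1e-12) + 1e-12).reshape(-1, 1)
        report = evaluate(fit, X, y)
        assert report.auc == pytest.approx(pair_counting_auc(y, scores), abs=1e-9)


def test_perfect_predictions_metrics():
    from divprop.classification import FitResult

    fit = FitResult(np.array([10.0]), 0.0, 1.0, np.zeros(1), np.ones(1))
    X = np.repeat([[1.0], [-1.0]], 10, axis=0)
    y = np.repeat([1, 0], 10)
    report = evaluate(fit, X, y)
    assert report.auc == 1.0
    assert report.f1 == 1.0
    assert report.confusion["tp"] == report.confusion["tn"] == 0.5
    assert sum(report.confusion.values()) == pytest.approx(1.0)


def test_constant_scorer_gives_tie_auc():
    from divprop.classification import FitResult

    fit = FitResult(np.array([0.0]), 0.0, 1.0, np.zeros(1), np.ones(1))
    X = np.zeros((10, 1))
    y = np.repeat([1, 0], 5)
    report = evaluate(fit, X, y)
    assert report.auc == pytest.approx(0.5)
    # probability exactly 0.5 -> everyone predicted positive at the 0.5 cut
    assert report.confusion["fn"] + report.confusion["tn"] == pytest.approx(0.0)


def test_single_class_evaluation_warns_but_keeps_f1():
    from divprop.classification import FitResult

    fit = FitResult(np.array([5.0]), 0.0, 1.0, np.zeros(1), np.ones(1))
    X = np.ones((6, 1))
    with pytest.warns(UserWarning, match="single-class"):
        report = evaluate(fit, X, np.ones(6, int))
    assert report.auc is None
    assert report.f1 == 1.0


def make_report(div, conf=None):
    conf = conf or {"tp": 0.25, "tn": 0.25, "fp": 0.25, "fn": 0.25}
    return MetricReport(auc=0.5, f1=0.5, confusion=conf, n=10, ood_diversity=div)


def test_confusion_chunks_sort_and_average():
    reports = [make_report(d, {"tp": d / 12, "tn": 1 - d / 12, "fp": 0, "fn": 0})
               for d in range(12, 0, -1)]
    chunks = confusion_by_diversity(reports, n_chunks=6)
    assert len(chunks) == 6
    assert chunks[0]["tp"] == pytest.approx((1 / 12 + 2 / 12) / 2)
    assert chunks[-1]["tp"] == pytest.approx((11 / 12 + 12 / 12) / 2)


def test_confusion_chunk_sizes_follow_remainder_rule():
    reports = [make_report(float(d)) for d in range(13)]
    chunks = confusion_by_diversity(reports, n_chunks=6)
    assert len(chunks) == 6  # sizes (3,2,2,2,2,2) verified via chunk_sizes tests
    with pytest.raises(ValueError, match="at least"):
        confusion_by_diversity(reports[:5], n_chunks=6)


def test_training_rejects_bad_inputs(rng):
    X = rng.normal(size=(20, 3))
    with pytest.raises(ValueError, match="single class"):
        train_classifier(X, np.zeros(20, int))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        train_classifier(X, np.repeat([0, 1], 10))
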