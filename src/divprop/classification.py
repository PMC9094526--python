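"""L2-penalized logistic classification of diagnosis from brain features.

The classifier minimizes the cost

    J(w) = -sum_i [ y_i log(phi(z_i)) + (1 - y_i) log(1 - phi(z_i)) ]
           + lambda * ||w||^2,

with z_i = w.x_i + b and phi the sigmoid; the intercept b is unpenalized.
The regularization strength lambda is tuned by an inner 5-fold CV over a
grid of 7 log-equidistant points in [1e-3, 1e+3], selecting by AUC (ties go
to the smallest lambda on the grid). Features are z-scored using statistics
of the training rows only; the stored parameters are re-applied to any
evaluation rows, so no information flows from test to fit.

The scikit-learn solver parameterizes the penalty as 0.5 ||w||^2 + C * loss,
so the exact conversion C = 1 / (2 * lambda) is applied to keep the grid in
the J(w) parameterization above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .stratification import chunk_sizes

__all__ = [
    "TrainingConfig",
    "FitResult",
    "MetricReport",
    "train_classifier",
    "evaluate",
    "cross_val_performance",
    "confusion_by_diversity",
    "cost_function",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3.0, 3.0, 7))


def _lambda_to_C(lam: float) -> float:
    # J(w) = loss + lam*||w||^2  <->  sklearn 0.5*||w||^2 + C*loss
    return 1.0 / (2.0 * lam)


@dataclass
class TrainingConfig:
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    inner_folds: int = 5
    outer_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.lambda_grid)
        if any(v <= 0 for v in grid) or list(grid) != sorted(grid):
            raise ValueError("lambda grid must be positive and ascending")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("fold counts must be at least 2")
        self.lambda_grid = grid


@dataclass
class FitResult:
    weights: np.ndarray
    intercept: float
    lam: float
    z_mean: np.ndarray
    z_sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.z_mean) / self.z_sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.transform(X) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MetricReport:
    auc: float | None
    f1: float
    confusion: dict[str, float]  # proportions tp/tn/fp/fn, summing to 1
    n: int
    by_group: dict = field(default_factory=dict)
    ood_diversity: float | None = None


def cost_function(
    weights: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray, lam: float
) -> float:
    """J(w) evaluated at given parameters (for optimizer sanity checks)."""
    z = X @ weights + intercept
    # log(phi) and log(1-phi) via the numerically stable logaddexp form
    loglik = -(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y)).sum()
    return float(-loglik + lam * np.dot(weights, weights))


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant feature -> centered zeros
    return mean, sd


def _fit_at_lambda(Xz: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    model = LogisticRegression(
        C=_lambda_to_C(lam), solver="lbfgs", max_iter=5000, tol=1e-8
    )
    model.fit(Xz, y)
    return model


def train_classifier(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None
) -> FitResult:
    """Fit the penalized logistic model with inner-CV lambda selection.

    With a single-point lambda grid the inner CV is skipped and the model is
    fitted directly at that lambda.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    _check_training_inputs(X, y)

    mean, sd = _zscore_params(X)
    Xz = (X - mean) / sd

    if len(config.lambda_grid) == 1:
        lam = config.lambda_grid[0]
    else:
        folds = min(config.inner_folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=config.seed)
        splits = list(skf.split(Xz, y))
        scores = np.zeros(len(config.lambda_grid))
        for tr, va in splits:
            for k, lam in enumerate(config.lambda_grid):
                model = _fit_at_lambda(Xz[tr], y[tr], lam)
                proba = model.predict_proba(Xz[va])[:, 1]
                if np.unique(y[va]).size < 2:
                    continue
                scores[k] += roc_auc_score(y[va], proba)
        lam = config.lambda_grid[int(np.argmax(scores))]

    final = _fit_at_lambda(Xz, y, lam)
    return FitResult(
        weights=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        lam=float(lam),
        z_mean=mean,
        z_sd=sd,
    )


def _confusion_proportions(y: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    n = y.size
    return {
        "tp": float(((pred == 1) & (y == 1)).sum() / n),
        "tn": float(((pred == 0) & (y == 0)).sum() / n),
        "fp": float(((pred == 1) & (y == 0)).sum() / n),
        "fn": float(((pred == 0) & (y == 1)).sum() / n),
    }


def evaluate(
    fit: FitResult,
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    ood_diversity: float | None = None,
) -> MetricReport:
    """AUC, F1 (0.5 threshold) and confusion proportions on evaluation rows.

    ``groups`` maps a grouping name (e.g. "site", "sex") to per-row labels;
    per-group confusion proportions are then reported alongside the overall
    ones. A single-class label vector leaves AUC undefined (None, with a
    warning); F1 and the confusion breakdown are still computed.
    """
    y = np.asarray(y, int).ravel()
    proba = fit.predict_proba(X)
    pred = (proba >= 0.5).astype(int)

    if np.unique(y).size < 2:
        warnings.warn("single-class evaluation labels: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(y, proba))
    f1 = float(f1_score(y, pred, zero_division=0.0))

    by_group: dict = {}
    if groups:
        for name, labels in groups.items():
            labels = np.asarray(labels)
            by_group[name] = {
                str(lvl): _confusion_proportions(y[labels == lvl], pred[labels == lvl])
                for lvl in np.unique(labels)
            }
    return MetricReport(
        auc=auc,
        f1=f1,
        confusion=_confusion_proportions(y, pred),
        n=int(y.size),
        by_group=by_group,
        ood_diversity=ood_diversity,
    )


def cross_val_performance(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None
) -> dict[str, float]:
    """Within-distribution performance: mean AUC/F1 over seeded outer folds.

    Outer folds are class-stratified random splits (propensity-agnostic);
    each fold runs the full fit (z-scoring + inner lambda tuning) on its
    training portion only.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    folds = min(config.outer_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=config.seed)
    aucs, f1s = [], []
    for tr, te in skf.split(X, y):
        fit = train_classifier(X[tr], y[tr], config)
        report = evaluate(fit, X[te], y[te])
        if report.auc is not None:
            aucs.append(report.auc)
        f1s.append(report.f1)
    return {"auc": float(np.mean(aucs)), "f1": float(np.mean(f1s))}


def confusion_by_diversity(
    reports: list[MetricReport], n_chunks: int = 6
) -> list[dict[str, float]]:
    """Average confusion proportions within diversity-ordered chunks.

    Reports are sorted ascending by their OOD diversity and split into
    ``n_chunks`` near-equal groups (remainder to the front); each chunk's
    confusion proportions are averaged entrywise.
    """
    if len(reports) < n_chunks:
        raise ValueError(f"need at least {n_chunks} reports, got {len(reports)}")
    if any(r.ood_diversity is None for r in reports):
        raise ValueError("every report needs an OOD diversity value")
    ordered = sorted(reports, key=lambda r: r.ood_diversity)
    sizes = chunk_sizes(len(ordered), n_chunks)
    out, start = [], 0
    for size in sizes:
        chunk = ordered[start : start + size]
        start += size
        out.append(
            {
                key: float(np.mean([r.confusion[key] for r in chunk]))
                for key in ("tp", "tn", "fp", "fn")
            }
        )
    return out
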