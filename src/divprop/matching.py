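"""Caliper-constrained optimal case-control pair matching and balance checks.

Cases are paired one-to-one with controls by minimizing the total absolute
propensity-score distance with the Hungarian algorithm (rectangular linear
sum assignment). Pairs whose distance exceeds the caliper -- 0.2 times the
standard deviation of pairwise absolute score differences -- are priced out
with a prohibitively large cost before assignment and discarded afterwards,
so every retained pair satisfies the caliper.

Balance is diagnosed with the absolute standardized mean difference (SMD):
``|x1 - x0| / sqrt((s1^2 + s0^2) / 2)`` for continuous covariates and the
analogous prevalence form for binary ones; SMD < 0.1 is the conventional
well-balanced threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .propensity import CovariateDesign

__all__ = [
    "MatchingConfig",
    "MatchedPair",
    "match_pairs",
    "caliper_threshold",
    "smd_continuous",
    "smd_binary",
    "balance_report",
    "covariate_informativeness_auc",
]

SMD_BALANCE_THRESHOLD = 0.1


@dataclass
class MatchingConfig:
    """Caliper settings.

    ``d_sd_mode`` selects the population over which the standard deviation of
    pairwise absolute score differences is taken: ``"all"`` (all participant
    pairs; default) or ``"cross"`` (case-control pairs only, i.e. exactly the
    costs fed to the assignment).
    """

    caliper_multiplier: float = 0.2
    d_sd_mode: str = "all"

    def __post_init__(self) -> None:
        if self.caliper_multiplier <= 0:
            raise ValueError("caliper_multiplier must be positive")
        if self.d_sd_mode not in ("cross", "all"):
            raise ValueError("d_sd_mode must be 'cross' or 'all'")


@dataclass(frozen=True)
class MatchedPair:
    case_id: object
    control_id: object
    distance: float
    mean_score: float


def caliper_threshold(
    scores_case: np.ndarray, scores_control: np.ndarray, config: MatchingConfig
) -> float:
    """Caliper distance 0.2 * d_sd for the given score lists."""
    a = np.asarray(scores_case, float)
    b = np.asarray(scores_control, float)
    if config.d_sd_mode == "cross":
        diffs = np.abs(a[:, None] - b[None, :]).ravel()
    else:
        pooled = np.concatenate([a, b])
        iu = np.triu_indices(pooled.size, k=1)
        diffs = np.abs(pooled[:, None] - pooled[None, :])[iu]
    return config.caliper_multiplier * float(diffs.std())


def match_pairs(
    scores_case,
    scores_control,
    config: MatchingConfig | None = None,
    case_ids=None,
    control_ids=None,
) -> list[MatchedPair]:
    """Optimal caliper-constrained 1:1 matching on propensity-score distance.

    Accepts pandas Series (ids taken from the index) or arrays with optional
    explicit id lists. With unequal group sizes, min(n_case, n_control)
    pairs are assigned before the caliper discard. Returns an empty list
    (with a warning) when no admissible pair survives.
    """
    config = config or MatchingConfig()
    if isinstance(scores_case, pd.Series):
        case_ids = scores_case.index.tolist()
        scores_case = scores_case.to_numpy()
    if isinstance(scores_control, pd.Series):
        control_ids = scores_control.index.tolist()
        scores_control = scores_control.to_numpy()
    a = np.asarray(scores_case, float).ravel()
    b = np.asarray(scores_control, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if case_ids is None:
        case_ids = list(range(a.size))
    if control_ids is None:
        control_ids = list(range(b.size))

    cost = np.abs(a[:, None] - b[None, :])
    threshold = caliper_threshold(a, b, config)
    admissible = cost <= threshold
    if admissible.any():
        forbidden_cost = 10.0 * (float(cost[admissible].max()) + 1.0)
    else:
        forbidden_cost = 10.0
    priced = np.where(admissible, cost, forbidden_cost)

    rows, cols = linear_sum_assignment(priced)
    pairs = [
        MatchedPair(
            case_id=case_ids[i],
            control_id=control_ids[j],
            distance=float(cost[i, j]),
            mean_score=float((a[i] + b[j]) / 2.0),
        )
        for i, j in zip(rows, cols)
        if cost[i, j] <= threshold
    ]
    if not pairs:
        warnings.warn("no admissible pairs within the caliper", stacklevel=2)
    return pairs


def smd_continuous(x1: np.ndarray, x0: np.ndarray) -> float:
    x1 = np.asarray(x1, float)
    x0 = np.asarray(x0, float)
    pooled = (x1.var() + x0.var()) / 2.0
    diff = abs(x1.mean() - x0.mean())
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


def smd_binary(p1: float, p0: float) -> float:
    pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    diff = abs(p1 - p0)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


def balance_report(
    design: CovariateDesign,
    labels: np.ndarray | pd.Series,
    subset_ids=None,
) -> pd.DataFrame:
    """Per-covariate absolute SMD between the diagnosis groups.

    ``subset_ids`` restricts the computation to those participants (e.g. the
    members of a matched pair set); by default all rows are used. Binary
    columns (sex and site indicators) use the prevalence formula; age uses
    the continuous formula. The ``balanced`` flag marks SMD < 0.1.
    """
    y = np.asarray(labels, int).ravel()
    if y.shape[0] != design.n:
        raise ValueError("labels do not match design rows")
    mask = np.ones(design.n, bool)
    if subset_ids is not None:
        wanted = set(subset_ids)
        mask = np.array([pid in wanted for pid in design.ids])
    X = design.matrix[mask]
    y = y[mask]
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both groups must be non-empty")

    records = []
    for k, name in enumerate(design.columns):
        x1, x0 = X[y == 1, k], X[y == 0, k]
        if set(np.unique(X[:, k])) <= {0.0, 1.0}:
            d = smd_binary(float(x1.mean()), float(x0.mean()))
            kind = "binary"
        else:
            d = smd_continuous(x1, x0)
            kind = "continuous"
        records.append(
            {
                "covariate": name,
                "kind": kind,
                "mean_case": float(x1.mean()),
                "mean_control": float(x0.mean()),
                "var_case": float(x1.var()),
                "var_control": float(x0.var()),
                "smd": d,
                "balanced": d < SMD_BALANCE_THRESHOLD,
            }
        )
    return pd.DataFrame.from_records(records)


def covariate_informativeness_auc(
    design: CovariateDesign,
    labels: np.ndarray | pd.Series,
    subset_ids=None,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated AUC of a covariate-only classifier of diagnosis.

    An audit of matching quality: before matching, confounded covariates
    predict diagnosis well above chance; after matching they should fall to
    chance (AUC near 0.5). Restricted to ``subset_ids`` when given.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, int).ravel()
    mask = np.ones(design.n, bool)
    if subset_ids is not None:
        wanted = set(subset_ids)
        mask = np.array([pid in wanted for pid in design.ids])
    X, y = design.matrix[mask], y[mask]
    folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(X, y):
        model = LogisticRegression(max_iter=2000).fit(X[tr], y[tr])
        if np.unique(y[te]).size == 2:
            aucs.append(roc_auc_score(y[te], model.predict_proba(X[te])[:, 1]))
    return float(np.mean(aucs))


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": p.case_id,
                "control_id": p.control_id,
                "distance": p.distance,
                "mean_score": p.mean_score,
            }
            for p in pairs
        ]
    )
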