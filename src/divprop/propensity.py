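"""Propensity-score estimation from participant covariates.

The propensity score pi = P(Y = 1 | C) is the probability that a participant
carries the diagnosis given demographic covariates only (age, sex, scanning
site) -- brain features never enter this model. It is estimated by logistic
regression of diagnosis on the encoded covariates, followed by a Platt
(sigmoid) recalibration so that class imbalance does not skew the
probabilities. The recalibration map is fitted on out-of-fold decision
scores from 5-fold cross-fitting.

The score acts as a balancing score: participants with similar scores have
similar joint covariate profiles, which is what the downstream matching,
stratification and diversity indices rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["CovariateDesign", "PropensityModel", "encode_covariates", "estimate_propensity"]

# Very weak ridge keeps the base fit well-posed under (quasi-)separation
# without materially shrinking coefficients.
_BASE_C = 1e4
_SCORE_CLIP = 1e-6

REQUIRED_COLUMNS = ("participant_id", "age", "sex", "site")


@dataclass
class CovariateDesign:
    """Encoded covariate matrix with the metadata needed to re-encode new rows.

    Columns: standardized age, binary sex, then one indicator per site level
    (in ``site_levels`` order).
    """

    ids: list
    matrix: np.ndarray
    columns: list[str]
    site_levels: list
    age_mean: float
    age_sd: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PropensityModel:
    """Fitted logit coefficients plus the Platt recalibration map."""

    coef: np.ndarray
    intercept: float
    platt_slope: float
    platt_offset: float
    design_meta: dict = field(default_factory=dict)

    def decision(self, design: CovariateDesign) -> np.ndarray:
        return design.matrix @ self.coef + self.intercept

    def predict(self, design: CovariateDesign) -> np.ndarray:
        """Calibrated propensity scores in (0, 1)."""
        z = self.platt_slope * self.decision(design) + self.platt_offset
        p = 1.0 / (1.0 + np.exp(-z))
        return np.clip(p, _SCORE_CLIP, 1.0 - _SCORE_CLIP)


def encode_covariates(
    phenotype: pd.DataFrame,
    site_levels: list | None = None,
    age_mean: float | None = None,
    age_sd: float | None = None,
) -> CovariateDesign:
    """Encode the phenotype table into a numeric design matrix.

    Age is z-scored (constants stored for re-encoding), sex is passed through
    as a 0/1 indicator, and site becomes a full one-hot block over
    ``site_levels``. Passing the metadata of a previous encoding reproduces
    that encoding exactly on new rows; an unseen site level is an error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in phenotype.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {missing}")
    for col in ("age", "sex", "site"):
        bad = phenotype.index[phenotype[col].isna()]
        if len(bad):
            raise ValueError(f"missing value in column {col!r} at row(s) {bad.tolist()}")

    age = phenotype["age"].to_numpy(dtype=float)
    if age_mean is None:
        age_mean = float(age.mean())
        sd = float(age.std())
        age_sd = sd if sd > 0 else 1.0
    age_z = (age - age_mean) / age_sd

    sex = phenotype["sex"].to_numpy(dtype=float)
    if not np.isin(sex, (0.0, 1.0)).all():
        raise ValueError("sex must be coded 0/1")

    sites = phenotype["site"].astype(str)
    if site_levels is None:
        site_levels = sorted(sites.unique())
    else:
        site_levels = [str(s) for s in site_levels]
        unseen = sorted(set(sites) - set(site_levels))
        if unseen:
            raise ValueError(f"unseen site level(s) at encoding time: {unseen}")
    onehot = np.column_stack([(sites == lvl).to_numpy(float) for lvl in site_levels])

    matrix = np.column_stack([age_z, sex, onehot])
    columns = ["age_z", "sex"] + [f"site_{lvl}" for lvl in site_levels]
    return CovariateDesign(
        ids=phenotype["participant_id"].tolist(),
        matrix=matrix,
        columns=columns,
        site_levels=list(site_levels),
        age_mean=age_mean,
        age_sd=age_sd,
    )


def _fit_base(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    model = LogisticRegression(C=_BASE_C, max_iter=2000, solver="lbfgs")
    model.fit(X, y)
    return model


def _fit_platt(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    calib = LogisticRegression(C=1e6, max_iter=2000, solver="lbfgs")
    calib.fit(scores.reshape(-1, 1), y)
    return float(calib.coef_[0, 0]), float(calib.intercept_[0])


def estimate_propensity(
    design: CovariateDesign,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
    n_calibration_folds: int = 5,
) -> tuple[PropensityModel, np.ndarray]:
    """Fit the propensity model and return calibrated scores per participant.

    The base logistic fit uses all rows; the Platt sigmoid is fitted on
    out-of-fold decision scores from ``n_calibration_folds``-fold
    cross-fitting so that the calibration map is not tuned on in-sample
    scores.
    """
    y = np.asarray(labels, dtype=int).ravel()
    if y.shape[0] != design.n:
        raise ValueError("labels do not match design rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both diagnosis classes must be present")
    if design.n <= design.matrix.shape[1]:
        warnings.warn(
            "fewer participants than design columns; propensity estimates "
            "may be unstable",
            stacklevel=2,
        )

    X = design.matrix
    base = _fit_base(X, y)

    oof = np.empty(design.n)
    skf = StratifiedKFold(n_splits=n_calibration_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        fold = _fit_base(X[train_idx], y[train_idx])
        oof[test_idx] = fold.decision_function(X[test_idx])
    slope, offset = _fit_platt(oof, y)

    model = PropensityModel(
        coef=base.coef_.ravel().copy(),
        intercept=float(base.intercept_[0]),
        platt_slope=slope,
        platt_offset=offset,
        design_meta={
            "columns": design.columns,
            "site_levels": design.site_levels,
            "age_mean": design.age_mean,
            "age_sd": design.age_sd,
        },
    )
    return model, model.predict(design)
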