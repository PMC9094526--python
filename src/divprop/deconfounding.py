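"""Covariate removal from feature matrices.

Two approaches are provided. *Linear residualization* regresses each
feature on the confound design (age, sex and/or site indicators) by
ordinary least squares and keeps the residuals, re-centered at the grand
mean; for a categorical confound this amounts to centering the data within
each level. *ComBat harmonization* fits the per-feature location-scale
site-effect model with parametric empirical-Bayes shrinkage of the
per-site parameters, protecting specified covariates (age, sex) by
including them in the standardization design; a second step then regresses
the protected covariates out with plain residualization. The two-step form
removes both additive and multiplicative site effects while never relying
on the site model to absorb age or sex variation.

Fitted transforms are stored so the identical adjustment can be applied to
new rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DeconfoundModel", "residualize", "combat_adjust"]


@dataclass
class DeconfoundModel:
    """Stored parameters of a fitted deconfounding transform."""

    method: str  # raw | linreg | combat
    params: dict = field(default_factory=dict)

    def apply(self, X: np.ndarray, confound_design: np.ndarray | None = None,
              site_labels=None) -> np.ndarray:
        """Apply the stored transform to new rows."""
        X = np.asarray(X, float)
        if self.method == "raw":
            return X.copy()
        if self.method == "linreg":
            D = np.asarray(confound_design, float)[:, self.params["kept_columns"]]
            return X - (D - self.params["col_means"]) @ self.params["beta"]
        if self.method == "combat":
            step1 = _combat_apply(X, site_labels, confound_design, self.params)
            return self.params["step2"].apply(step1, confound_design)
        raise ValueError(f"unknown method {self.method!r}")


def _independent_columns(D: np.ndarray) -> list[int]:
    """Greedy left-to-right selection of columns independent of the intercept.

    The residualization always fits an (implicit) intercept, so a column is
    dropped when it is collinear with the intercept plus the columns already
    kept (e.g. the last indicator of a full one-hot block).
    """
    ones = np.ones((D.shape[0], 1))
    kept: list[int] = []
    for j in range(D.shape[1]):
        trial = np.column_stack([ones, D[:, kept + [j]]])
        if np.linalg.matrix_rank(trial) == len(kept) + 2:
            kept.append(j)
    return kept


def residualize(
    features: np.ndarray, confound_design: np.ndarray
) -> tuple[np.ndarray, DeconfoundModel]:
    """OLS residuals of each feature on the confounds, grand mean retained.

    Confound columns are centered before the fit, so the residuals keep each
    feature's overall mean; the stored coefficients and column means let the
    identical transform be applied to new rows. Collinear confound columns
    are dropped with a warning.
    """
    X = np.asarray(features, float)
    D = np.asarray(confound_design, float)
    if D.ndim == 1:
        D = D[:, None]
    if X.shape[0] <= D.shape[1]:
        raise ValueError(
            f"need more rows ({X.shape[0]}) than confound columns ({D.shape[1]})"
        )
    kept = _independent_columns(D)
    if len(kept) < D.shape[1]:
        warnings.warn(
            f"dropped {D.shape[1] - len(kept)} collinear confound column(s)",
            stacklevel=2,
        )
    D = D[:, kept]
    col_means = D.mean(axis=0)
    Dc = D - col_means
    beta, *_ = np.linalg.lstsq(Dc, X, rcond=None)
    model = DeconfoundModel(
        "linreg", {"kept_columns": kept, "col_means": col_means, "beta": beta}
    )
    return X - Dc @ beta, model


# ---------------------------------------------------------------------------
# parametric empirical-Bayes ComBat


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else m


def _eb_site_params(Z_site: np.ndarray, gamma_hat: np.ndarray, tol: float = 1e-6):
    """Iterative EB posterior estimates of one site's location/scale effects."""
    n = Z_site.shape[0]
    delta_hat = Z_site.var(axis=0, ddof=1)
    g_bar, t2 = gamma_hat.mean(), gamma_hat.var()
    a, b = _aprior(delta_hat), _bprior(delta_hat)
    g_new, d_new = gamma_hat.copy(), delta_hat.copy()
    if t2 == 0:  # single feature: no shrinkage possible
        return g_new, np.maximum(d_new, 1e-12)
    for _ in range(200):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * gamma_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((Z_site - g_new) ** 2).sum(axis=0)
        d_new = (b + 0.5 * sum2) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
            np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
        )
        if change < tol:
            break
    return g_new, np.maximum(d_new, 1e-12)


def _combat_apply(X, site_labels, preserve_design, params) -> np.ndarray:
    site_labels = np.asarray(site_labels)
    M = np.asarray(preserve_design, float) if preserve_design is not None else None
    stand_mean = params["grand_mean"][None, :].repeat(X.shape[0], axis=0)
    if M is not None and params["beta_cov"] is not None:
        stand_mean = stand_mean + M @ params["beta_cov"]
    out = X.copy()
    active = params["active"]
    sigma = np.sqrt(params["var_pooled"][active])
    Z = (X[:, active] - stand_mean[:, active]) / sigma
    for lvl, (gamma, delta) in params["site_effects"].items():
        rows = site_labels == lvl
        if rows.any():
            Z[rows] = (Z[rows] - gamma) / np.sqrt(delta)
    out[:, active] = Z * sigma + stand_mean[:, active]
    return out


def combat_adjust(
    features: np.ndarray,
    site_labels,
    preserve_design: np.ndarray | None,
    residualize_covariates: bool = True,
) -> tuple[np.ndarray, DeconfoundModel]:
    """Two-step harmonization: EB site-effect removal, then covariate residuals.

    Step 1 standardizes each feature with a design containing site
    indicators plus the preserved covariates, shrinks the per-site additive
    and multiplicative effects toward their parametric empirical-Bayes
    priors, and removes them. Step 2 residualizes the preserved covariates
    (age, sex) out of the harmonized data; site is already handled, so it
    does not re-enter the regression. ``residualize_covariates=False``
    stops after step 1 (harmonized data with covariate variation intact).
    Constant features pass through unchanged with a warning.
    """
    X = np.asarray(features, float)
    site_labels = np.asarray(site_labels)
    levels, counts = np.unique(site_labels, return_counts=True)
    singletons = levels[counts < 2]
    if singletons.size:
        raise ValueError(
            f"site(s) with a single participant: {singletons.tolist()}"
        )
    n = X.shape[0]
    B = np.column_stack([(site_labels == lvl).astype(float) for lvl in levels])
    M = np.asarray(preserve_design, float) if preserve_design is not None else None
    if M is not None and M.ndim == 1:
        M = M[:, None]
    design = B if M is None else np.column_stack([B, M])

    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    site_means = beta[: len(levels)]
    beta_cov = beta[len(levels):] if M is not None else None
    grand_mean = (counts / n) @ site_means
    resid = X - design @ beta
    var_pooled = (resid**2).mean(axis=0)

    active = (X.std(axis=0) > 0) & (var_pooled > 0)
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} constant feature(s) skipped by ComBat",
            stacklevel=2,
        )

    stand_mean = grand_mean[None, :].repeat(n, axis=0)
    if M is not None:
        stand_mean = stand_mean + M @ beta_cov
    sigma = np.sqrt(var_pooled[active])
    Z = (X[:, active] - stand_mean[:, active]) / sigma

    site_effects: dict = {}
    Z_adj = Z.copy()
    for k, lvl in enumerate(levels):
        rows = site_labels == lvl
        gamma_hat = Z[rows].mean(axis=0)
        gamma_star, delta_star = _eb_site_params(Z[rows], gamma_hat)
        site_effects[lvl] = (gamma_star, delta_star)
        Z_adj[rows] = (Z[rows] - gamma_star) / np.sqrt(delta_star)

    step1 = X.copy()
    step1[:, active] = Z_adj * sigma + stand_mean[:, active]

    params = {
        "grand_mean": grand_mean,
        "beta_cov": beta_cov,
        "var_pooled": var_pooled,
        "active": active,
        "site_effects": site_effects,
        "site_levels": levels.tolist(),
    }

    if M is not None and residualize_covariates:
        harmonized, step2 = residualize(step1, M)
    else:
        harmonized, step2 = step1, DeconfoundModel("raw")
    params["step2"] = step2
    return harmonized, DeconfoundModel("combat", params)
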