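"""End-to-end experiment orchestration.

Runs the full chain from a single configuration: build or load the cohort,
optionally deconfound the features (cohort-wide before matching by default,
matching the framework's protocol; a strict train-only mode refits the
deconfounding model inside every draw), estimate propensity scores from
covariates, match cases to controls within the caliper, stratify the pairs,
enumerate train/holdout draws, fit the penalized logistic classifier per
draw, and evaluate within-distribution (10-fold CV on the training pairs)
and out-of-distribution performance (per holdout stratum, never pooled).

Diversity-performance correlations are computed with one point per draw
(WD) and one point per (draw, holdout stratum) pair (OOD).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    MetricReport,
    TrainingConfig,
    cross_val_performance,
    evaluate,
    train_classifier,
)
from .deconfounding import combat_adjust, residualize
from .features import FeatureMatrix
from .matching import MatchingConfig, balance_report, match_pairs
from .propensity import encode_covariates, estimate_propensity
from .sampling import Draw, enumerate_draws
from .stability import CoefficientCollection, consistency_matrix
from .stratification import Stratification, stratify
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "deconfound_features",
    "performance_diversity_correlations",
]


@dataclass
class ExperimentConfig:
    cohort: CohortSpec | None = None
    pheno: pd.DataFrame | None = None
    features: FeatureMatrix | None = None
    deconfound: str = "raw"  # raw | linreg | combat
    deconfound_scope: str = "cohort"  # cohort (pre-matching) | train (per draw)
    q: int = 10
    schemes: Sequence[str] = ("contiguous", "diverse", "random")
    r_values: Sequence[int] = tuple(range(2, 9))
    n_draws: int = 20
    exhaustive: bool = False  # scheme "all" at r = q // 2 (252 draws at q=10)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    compute_wd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deconfound not in ("raw", "linreg", "combat"):
            raise ValueError(f"unknown deconfound method {self.deconfound!r}")
        if self.deconfound_scope not in ("cohort", "train"):
            raise ValueError("deconfound_scope must be 'cohort' or 'train'")
        for r in self.r_values:
            if not (2 <= r <= self.q - 1):
                raise ValueError(f"r={r} outside [2, {self.q - 1}]")


@dataclass
class DrawResult:
    scheme: str
    r: int
    draw: Draw
    lam: float
    weights: np.ndarray
    wd_metrics: dict | None
    ood_reports: dict[int, MetricReport]


@dataclass
class ExperimentResult:
    pheno: pd.DataFrame
    scores: pd.Series
    pairs: list
    balance_before: pd.DataFrame
    balance_after: pd.DataFrame
    stratification: Stratification
    draw_results: list[DrawResult]
    manifest: dict

    def coefficient_collection(self) -> CoefficientCollection:
        return CoefficientCollection(
            weights=np.vstack([d.weights for d in self.draw_results]),
            wd=np.array([d.draw.wd for d in self.draw_results]),
        )

    def consistency(self) -> np.ndarray:
        return consistency_matrix(self.coefficient_collection())

    def to_json(self) -> str:
        payload = {
            "manifest": self.manifest,
            "n_pairs": len(self.pairs),
            "draws": [
                {
                    "scheme": d.scheme,
                    "r": d.r,
                    "train_strata": d.draw.train_strata,
                    "wd_diversity": d.draw.wd,
                    "lambda": d.lam,
                    "wd_metrics": d.wd_metrics,
                    "ood": {
                        str(s): {
                            "diversity": rep.ood_diversity,
                            "auc": rep.auc,
                            "f1": rep.f1,
                            "confusion": rep.confusion,
                            "n": rep.n,
                        }
                        for s, rep in d.ood_reports.items()
                    },
                }
                for d in self.draw_results
            ],
        }
        return json.dumps(payload, indent=2, default=float)


def deconfound_features(
    X: np.ndarray, pheno: pd.DataFrame, method: str
) -> np.ndarray:
    """Apply the configured deconfounding method cohort-wide."""
    if method == "raw":
        return np.asarray(X, float)
    age_z = stats.zscore(pheno["age"].to_numpy(float))
    sex = pheno["sex"].to_numpy(float)
    sites = pheno["site"].astype(str)
    if method == "linreg":
        # drop-first site coding: the intercept absorbs the reference level
        onehot = np.column_stack(
            [(sites == lvl).to_numpy(float) for lvl in sorted(sites.unique())[1:]]
        ) if sites.nunique() > 1 else np.empty((len(sites), 0))
        design = np.column_stack([age_z, sex, onehot])
        adjusted, _ = residualize(X, design)
        return adjusted
    if method == "combat":
        preserve = np.column_stack([age_z, sex])
        adjusted, _ = combat_adjust(X, sites.to_numpy(), preserve)
        return adjusted
    raise ValueError(f"unknown method {method!r}")


def _pair_row_indices(pairs, id_to_row) -> dict:
    """Map each global pair index to its two participant row indices."""
    return {
        k: (id_to_row[p.case_id], id_to_row[p.control_id])
        for k, p in enumerate(pairs)
    }


def _rows_for(pair_indices, pair_rows) -> np.ndarray:
    return np.array([r for k in pair_indices for r in pair_rows[k]])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute every enabled stage and collect the result bundle."""
    # ---- data ----------------------------------------------------------
    if config.cohort is not None:
        pheno, features, _truth = generate_cohort(config.cohort, seed=config.seed)
    elif config.pheno is not None and config.features is not None:
        pheno, features = config.pheno.reset_index(drop=True), config.features
    else:
        raise ValueError("config needs either a cohort spec or pheno + features")
    X_raw = features.values
    y_all = pheno["diagnosis"].to_numpy(int)

    manifest = {
        "seed": config.seed,
        "deconfound": config.deconfound,
        "deconfound_scope": config.deconfound_scope,
        "q": config.q,
        "pheno_digest": hashlib.sha256(
            pd.util.hash_pandas_object(pheno, index=False).to_numpy().tobytes()
        ).hexdigest()[:16],
        "features_digest": hashlib.sha256(X_raw.tobytes()).hexdigest()[:16],
    }

    # ---- deconfounding (cohort-wide protocol) --------------------------
    if config.deconfound_scope == "cohort":
        X = deconfound_features(X_raw, pheno, config.deconfound)
    else:
        X = np.asarray(X_raw, float)  # per-draw refit below

    # ---- propensity ----------------------------------------------------
    design = encode_covariates(pheno)
    _model, scores = estimate_propensity(design, y_all, seed=config.seed)
    score_series = pd.Series(scores, index=pheno["participant_id"].tolist())

    # ---- matching + balance -------------------------------------------
    case_scores = score_series[pheno.loc[y_all == 1, "participant_id"]]
    control_scores = score_series[pheno.loc[y_all == 0, "participant_id"]]
    pairs = match_pairs(case_scores, control_scores, config.matching)
    if len(pairs) < config.q:
        raise RuntimeError(
            f"matching retained {len(pairs)} pairs; need at least q={config.q}"
        )
    matched_ids = [pid for p in pairs for pid in (p.case_id, p.control_id)]
    balance_before = balance_report(design, y_all)
    balance_after = balance_report(design, y_all, subset_ids=matched_ids)

    # ---- stratification + draws ---------------------------------------
    strat = stratify(pairs, q=config.q)
    id_to_row = {pid: i for i, pid in enumerate(pheno["participant_id"])}
    pair_rows = _pair_row_indices(strat.all_pairs(), id_to_row)
    score_map = score_series.to_dict()

    draw_plan: list[tuple[str, int, Draw]] = []
    if config.exhaustive:
        r = config.q // 2
        for d in enumerate_draws(strat, "all", r, seed=config.seed, scores=score_map):
            draw_plan.append(("all", r, d))
    else:
        for scheme in config.schemes:
            for r in config.r_values:
                draws = enumerate_draws(
                    strat, scheme, r, n_draws=config.n_draws,
                    seed=config.seed, scores=score_map,
                )
                if not draws:
                    warnings.warn(
                        f"no {scheme} draws at r={r} (q={config.q})", stacklevel=2
                    )
                draw_plan.extend((scheme, r, d) for d in draws)

    # ---- fit + evaluate per draw --------------------------------------
    results: list[DrawResult] = []
    sites_all = pheno["site"].astype(str).to_numpy()
    sex_all = pheno["sex"].to_numpy(int)
    for scheme, r, draw in draw_plan:
        train_rows = _rows_for(draw.train_pair_indices, pair_rows)
        if config.deconfound_scope == "train":
            Xd = _train_scope_deconfound(X, pheno, train_rows, config.deconfound)
        else:
            Xd = X
        fit = train_classifier(Xd[train_rows], y_all[train_rows], config.training)
        wd_metrics = (
            cross_val_performance(Xd[train_rows], y_all[train_rows], config.training)
            if config.compute_wd
            else None
        )
        ood_reports: dict[int, MetricReport] = {}
        for s, div in draw.ood.items():
            if s == -1:
                rows = _rows_for(draw.holdout_pair_indices, pair_rows)
            else:
                start = sum(len(strat.strata[i]) for i in range(s))
                rows = _rows_for(range(start, start + len(strat.strata[s])), pair_rows)
            ood_reports[s] = evaluate(
                fit,
                Xd[rows],
                y_all[rows],
                groups={"site": sites_all[rows], "sex": sex_all[rows]},
                ood_diversity=div,
            )
        results.append(
            DrawResult(scheme, r, draw, fit.lam, fit.weights, wd_metrics, ood_reports)
        )

    return ExperimentResult(
        pheno=pheno,
        scores=score_series,
        pairs=pairs,
        balance_before=balance_before,
        balance_after=balance_after,
        stratification=strat,
        draw_results=results,
        manifest=manifest,
    )


def _train_scope_deconfound(X, pheno, train_rows, method) -> np.ndarray:
    """Leakage-safe variant: fit the deconfounder on training rows only."""
    if method == "raw":
        return np.asarray(X, float)
    sub_pheno = pheno.iloc[train_rows]
    age_mu = sub_pheno["age"].mean()
    age_sd = max(sub_pheno["age"].std(ddof=0), 1e-12)
    age_z = (pheno["age"].to_numpy(float) - age_mu) / age_sd
    sex = pheno["sex"].to_numpy(float)
    sites = pheno["site"].astype(str)
    levels = sorted(sub_pheno["site"].astype(str).unique())[1:]  # drop-first
    onehot = (
        np.column_stack([(sites == lvl).to_numpy(float) for lvl in levels])
        if levels else np.empty((len(sites), 0))
    )
    if method == "linreg":
        design = np.column_stack([age_z, sex, onehot])
        _, model = residualize(X[train_rows], design[train_rows])
        return model.apply(X, design)
    preserve = np.column_stack([age_z, sex])
    _, model = combat_adjust(
        X[train_rows], sites.to_numpy()[train_rows], preserve[train_rows]
    )
    return model.apply(X, preserve, sites.to_numpy())


def performance_diversity_correlations(result: ExperimentResult) -> dict:
    """Pearson r between diversity and AUC/F1, WD and OOD views.

    WD uses one point per draw (training diversity vs 10-fold CV
    performance); OOD uses one point per (draw, holdout stratum) pair.
    """
    out: dict = {}
    wd_x, wd_auc, wd_f1 = [], [], []
    for d in result.draw_results:
        if d.wd_metrics is not None:
            wd_x.append(d.draw.wd)
            wd_auc.append(d.wd_metrics["auc"])
            wd_f1.append(d.wd_metrics["f1"])
    if len(wd_x) >= 3 and np.std(wd_x) > 0:
        out["wd_auc_r"] = float(stats.pearsonr(wd_x, wd_auc)[0])
        out["wd_f1_r"] = float(stats.pearsonr(wd_x, wd_f1)[0])

    ood_x, ood_auc, ood_f1 = [], [], []
    for d in result.draw_results:
        for rep in d.ood_reports.values():
            if rep.auc is not None:
                ood_x.append(rep.ood_diversity)
                ood_auc.append(rep.auc)
                ood_f1.append(rep.f1)
    if len(ood_x) >= 3 and np.std(ood_x) > 0:
        out["ood_auc_r"] = float(stats.pearsonr(ood_x, ood_auc)[0])
        out["ood_f1_r"] = float(stats.pearsonr(ood_x, ood_f1)[0])
    out["n_wd_points"] = len(wd_x)
    out["n_ood_points"] = len(ood_x)
    return out
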