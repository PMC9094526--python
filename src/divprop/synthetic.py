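"""Seeded synthetic multi-site cohorts for exercising the whole framework.

The generator emulates the statistical structure the diversity framework
assumes: several scanning sites with site-specific sex ratios and age
distributions, a diagnosis assigned from a logistic model on the covariates
(so a true propensity gradient exists and lies in the fitted model's
family), features carrying a group effect whose magnitude varies along the
propensity spectrum, additive/multiplicative site batch effects, and
Gaussian noise.

Effect-size scenarios (Delta x as a function of the true propensity pi):

- ``abide-like``:  Delta x(pi) = a * (1 - |2 pi - 1|)^gamma  -- largest at
  mid-spectrum, vanishing toward the extremes (groups are hardest to
  separate for the most extreme covariate profiles);
- ``hbn-like``:    Delta x(pi) = a * |2 pi - 1|^gamma -- smallest at
  mid-spectrum, growing toward the extremes;
- ``constant``:    Delta x = a everywhere;
- ``null``:        Delta x = 0 (no signal).

All randomness flows from a single seed through named substreams, so a
fixed (spec, seed) yields bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "SiteSpec",
    "CohortSpec",
    "delta_x",
    "generate_cohort",
    "generate_toy_single_feature",
    "abide_like_spec",
    "hbn_like_spec",
    "confounded_cohort_spec",
]

_MIN_TOY_N = 80  # enough participants for ~10 post-matching strata


@dataclass
class SiteSpec:
    """Composition and batch effects of one scanning site."""

    name: str
    n: int
    male_fraction: float = 0.8
    age_mean: float = 15.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (5.0, 45.0)
    site_coef: float = 0.0  # contribution to the diagnosis log odds
    offset: float = 0.0  # additive batch effect on every feature
    scale: float = 1.0  # multiplicative batch effect


@dataclass
class CohortSpec:
    """Full generative specification of a synthetic cohort."""

    sites: list[SiteSpec]
    n_features: int = 1
    scenario: str = "constant"
    effect_size: float = 1.5  # a, in units of noise_sd
    effect_gamma: float = 1.0  # gamma, shape exponent of Delta x(pi)
    noise_sd: float = 1.0
    age_coef: float = 1.2  # log-odds per SD of age
    sex_coef: float = 0.8  # log-odds for male vs female
    intercept: float | None = None  # None -> centered for ~balanced classes
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site is required")
        for s in self.sites:
            if s.n < 1:
                raise ValueError(f"site {s.name!r} has no participants")
            if not (0.0 <= s.male_fraction <= 1.0):
                raise ValueError(f"site {s.name!r}: male_fraction outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.scenario not in ("abide-like", "hbn-like", "constant", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def delta_x(pi: np.ndarray, scenario: str, a: float, gamma: float) -> np.ndarray:
    """Group-wise feature difference as a function of the propensity score."""
    pi = np.asarray(pi, float)
    if scenario == "abide-like":
        return a * (1.0 - np.abs(2 * pi - 1)) ** gamma
    if scenario == "hbn-like":
        return a * np.abs(2 * pi - 1) ** gamma
    if scenario == "constant":
        return np.full_like(pi, a)
    if scenario == "null":
        return np.zeros_like(pi)
    raise ValueError(f"unknown scenario {scenario!r}")


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, FeatureMatrix, pd.DataFrame]:
    """Sample one cohort: phenotype table, feature matrix, ground truth.

    Returns ``(pheno, features, truth)`` with aligned rows. ``pheno`` has
    columns participant_id, age, sex (1 = male), site, diagnosis; ``truth``
    records the generative propensity ``pi_true`` and effect ``delta_x``
    per participant.
    """
    seed = spec.seed if seed is None else seed
    rng_cov, rng_lab, rng_noise = np.random.default_rng(seed).spawn(3)

    rows = []
    for site in spec.sites:
        age = rng_cov.normal(site.age_mean, site.age_sd, size=site.n)
        age = np.clip(age, *site.age_range)
        male = (rng_cov.random(site.n) < site.male_fraction).astype(int)
        for a_val, m in zip(age, male):
            rows.append({"age": float(a_val), "sex": int(m), "site": site.name,
                         "site_coef": site.site_coef, "offset": site.offset,
                         "scale": site.scale})
    pheno = pd.DataFrame(rows)
    n = len(pheno)
    pheno.insert(0, "participant_id", [f"sub-{i:05d}" for i in range(n)])

    age_z = (pheno["age"] - pheno["age"].mean()) / max(pheno["age"].std(ddof=0), 1e-12)
    logit = (
        spec.age_coef * age_z.to_numpy()
        + spec.sex_coef * pheno["sex"].to_numpy()
        + pheno["site_coef"].to_numpy()
    )
    intercept = -float(np.mean(logit)) if spec.intercept is None else spec.intercept
    pi_true = 1.0 / (1.0 + np.exp(-(intercept + logit)))
    y = (rng_lab.random(n) < pi_true).astype(int)
    pheno["diagnosis"] = y

    dx = delta_x(pi_true, spec.scenario, spec.effect_size * spec.noise_sd,
                 spec.effect_gamma)
    noise = rng_noise.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    signal = (y - 0.5)[:, None] * dx[:, None]
    offset = pheno.pop("offset").to_numpy()[:, None]
    scale = pheno.pop("scale").to_numpy()[:, None]
    pheno.pop("site_coef")
    X = offset + scale * (signal + noise)

    features = FeatureMatrix(
        participant_ids=pheno["participant_id"].tolist(),
        values=X,
        feature_labels=list(range(spec.n_features)),
        modality="thickness",
    )
    truth = pd.DataFrame(
        {
            "participant_id": pheno["participant_id"],
            "pi_true": pi_true,
            "delta_x": dx,
        }
    )
    return pheno, features, truth


def generate_toy_single_feature(
    scenario: str, n: int = 1000, seed: int = 0, effect_size: float = 1.5
) -> tuple[pd.DataFrame, FeatureMatrix, pd.DataFrame]:
    """Single-feature, single-site toy cohort with a wide propensity spread.

    Suitable for the full match -> stratify -> draw -> fit -> evaluate
    chain; the covariate coefficients are strong enough that estimated
    propensity scores span most of (0, 1).
    """
    if scenario not in ("abide-like", "hbn-like", "null", "constant"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if n < _MIN_TOY_N:
        raise ValueError(
            f"n={n} is too small to fill 10 strata after matching; "
            f"need at least {_MIN_TOY_N}"
        )
    spec = CohortSpec(
        sites=[SiteSpec("S1", n, male_fraction=0.7, age_mean=12.0, age_sd=3.5)],
        n_features=1,
        scenario=scenario,
        effect_size=effect_size,
        effect_gamma=1.0,
        noise_sd=1.0,
        age_coef=1.4,
        sex_coef=1.0,
        seed=seed,
    )
    return generate_cohort(spec)


def abide_like_spec(scale: float = 1.0, scenario: str = "abide-like",
                    n_features: int = 1, seed: int = 0) -> CohortSpec:
    """Four-site cohort mirroring the ABIDE composition used in the analyses.

    Site sizes, sex ratios and age distributions follow the demographics of
    the four retained acquisition sites (NYU, PITT, TCD, USM); mild
    site-level log-odds shifts induce the site-diagnosis association that
    matching must remove. ``scale`` shrinks all site sizes proportionally.
    """
    sites = [
        SiteSpec("NYU", max(int(126 * scale), 2), 0.96, 15.0, 7.4, (6.0, 40.0), -0.2),
        SiteSpec("PITT", max(int(42 * scale), 2), 1.0, 20.2, 7.1, (9.0, 45.0), 0.1),
        SiteSpec("TCD", max(int(37 * scale), 2), 1.0, 15.1, 3.2, (9.0, 26.0), 0.0),
        SiteSpec("USM", max(int(92 * scale), 2), 1.0, 22.6, 7.7, (9.0, 50.0), 0.4),
    ]
    return CohortSpec(sites=sites, n_features=n_features, scenario=scenario,
                      age_coef=0.4, sex_coef=0.8, seed=seed)


def hbn_like_spec(scale: float = 1.0, scenario: str = "hbn-like",
                  n_features: int = 1, seed: int = 0) -> CohortSpec:
    """Three-site cohort mirroring the HBN autism-analysis composition.

    Sex ratios differ strongly between sites (females concentrated at SI),
    which is the main driver of the wide propensity spread this cohort is
    meant to reproduce. Site batch effects on features are switched on by
    default so harmonization has something to remove.
    """
    sites = [
        SiteSpec("CBIC", max(int(64 * scale), 2), 0.75, 12.2, 3.7, (5.0, 22.0),
                 0.6, offset=0.3, scale=1.2),
        SiteSpec("RU", max(int(82 * scale), 2), 0.67, 12.2, 3.8, (5.0, 22.0),
                 0.3, offset=-0.2, scale=0.9),
        SiteSpec("SI", max(int(62 * scale), 2), 0.50, 12.1, 3.6, (5.0, 22.0),
                 -0.9, offset=0.0, scale=1.0),
    ]
    return CohortSpec(sites=sites, n_features=n_features, scenario=scenario,
                      age_coef=0.4, sex_coef=1.2, seed=seed)


def confounded_cohort_spec(n: int = 400, seed: int = 0) -> CohortSpec:
    """Two-site null-signal cohort with strong covariate-diagnosis coupling.

    Covariates are informative about diagnosis (age, sex and site all carry
    log-odds), but features carry no group effect, so any predictive skill
    must come from confounding. Used to audit that matching removes the
    covariates' informativeness.
    """
    half = n // 2
    sites = [
        SiteSpec("A", half, 0.85, 11.0, 3.0, (5.0, 25.0), 0.8),
        SiteSpec("B", n - half, 0.45, 15.0, 4.0, (5.0, 30.0), -0.8),
    ]
    return CohortSpec(sites=sites, n_features=5, scenario="null",
                      age_coef=0.9, sex_coef=1.0, seed=seed)
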