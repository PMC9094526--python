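import numpy as np
import pandas as pd
import pytest

from divprop.matching import smd_continuous
from divprop.propensity import encode_covariates, estimate_propensity


def make_pheno(n, rng, sites=("A", "B", "C")):
    return pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "age": rng.normal(12, 3, n),
            "sex": rng.integers(0, 2, n),
            "site": rng.choice(sites, n),
        }
    )


def test_design_has_age_sex_and_site_block(rng):
    pheno = make_pheno(4, rng)
    pheno["site"] = ["A", "B", "C", "A"]
    design = encode_covariates(pheno)
    assert design.matrix.shape == (4, 5)  # age + sex + 3 sites
    site_block = design.matrix[:, 2:]
    assert np.allclose(site_block.sum(axis=1), 1.0)  # one site active per row


def test_single_site_all_male_design_degenerates_cleanly():
    pheno = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "age": [10.0, 12.0, 14.0],
            "sex": [1, 1, 1],
            "site": ["X", "X", "X"],
        }
    )
    design = encode_covariates(pheno)
    assert np.allclose(design.matrix[:, 1], 1.0)
    assert np.allclose(design.matrix[:, 2], 1.0)


def test_reencoding_with_stored_metadata_is_bit_exact(rng):
    pheno = make_pheno(50, rng)
    d1 = encode_covariates(pheno)
    d2 = encode_covariates(
        pheno, site_levels=d1.site_levels, age_mean=d1.age_mean, age_sd=d1.age_sd
    )
    assert np.array_equal(d1.matrix, d2.matrix)


def test_unseen_site_level_is_an_encoding_error(rng):
    pheno = make_pheno(10, rng)
    with pytest.raises(ValueError, match="unseen site"):
        encode_covariates(pheno, site_levels=["Z"])


def test_missing_covariate_names_row_and_column(rng):
    pheno = make_pheno(5, rng)
    pheno.loc[2, "age"] = np.nan
    with pytest.raises(ValueError, match="age"):
        encode_covariates(pheno)


def test_uninformative_covariates_give_scores_near_prevalence(rng):
    pheno = make_pheno(2000, rng)
    y = rng.integers(0, 2, 2000)
    design = encode_covariates(pheno)
    _, scores = estimate_propensity(design, y, seed=0)
    assert np.all((scores > 0) & (scores < 1))
    assert abs(scores.mean() - 0.5) < 0.03
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(y, scores) < 0.55


def test_calibrated_scores_recover_conditional_frequencies(rng):
    # single binary covariate: P(Y=1|c=1)=0.8, P(Y=1|c=0)=0.2
    n = 4000
    c = rng.integers(0, 2, n)
    y = (rng.random(n) < np.where(c == 1, 0.8, 0.2)).astype(int)
    pheno = pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "age": np.zeros(n),
            "sex": c,
            "site": ["A"] * n,
        }
    )
    design = encode_covariates(pheno)
    _, scores = estimate_propensity(design, y, seed=0)
    assert scores[c == 1].mean() == pytest.approx(0.8, abs=0.05)
    assert scores[c == 0].mean() == pytest.approx(0.2, abs=0.05)


def test_class_imbalance_scores_concentrate_near_prevalence(rng):
    n = 2000
    pheno = make_pheno(n, rng)
    y = (rng.random(n) < 0.25).astype(int)
    design = encode_covariates(pheno)
    _, scores = estimate_propensity(design, y, seed=0)
    assert abs(scores.mean() - y.mean()) < 0.05


def test_single_class_labels_rejected(rng):
    pheno = make_pheno(20, rng)
    with pytest.raises(ValueError, match="both"):
        estimate_propensity(encode_covariates(pheno), np.ones(20, int))


def test_balancing_property_within_score_bins():
    # informative covariates: within narrow score bins the two diagnosis
    # groups should have matched covariate distributions (balancing score);
    # the property is asymptotic, so a large cohort and narrow bins
    rng = np.random.default_rng(12345)  # local stream: bands are tight
    n = 20000
    age = rng.normal(12, 3, n)
    sex = rng.integers(0, 2, n)
    logit = 0.8 * (age - 12) / 3 + 1.0 * sex - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    pheno = pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "age": age,
            "sex": sex,
            "site": ["A"] * n,
        }
    )
    design = encode_covariates(pheno)
    _, scores = estimate_propensity(design, y, seed=0)
    bins = np.quantile(scores, np.linspace(0, 1, 26))
    smds = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (scores >= lo) & (scores < hi)
        if min((y[sel] == 1).sum(), (y[sel] == 0).sum()) < 30:
            continue
        smds.append(smd_continuous(age[sel & (y == 1)], age[sel & (y == 0)]))
    assert len(smds) >= 10
    assert np.mean(smds) < 0.1  # balanced within bins on average
    assert max(smds) < 0.3  # residual gradient only in the extreme bins


def test_reliability_slope_near_unity_on_large_cohort(rng):
    n = 6000
    age = rng.normal(0, 1, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-1.2 * age))).astype(int)
    pheno = pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "age": age,
            "sex": np.zeros(n, int),
            "site": ["A"] * n,
        }
    )
    _, scores = estimate_propensity(encode_covariates(pheno), y, seed=0)
    # regression of outcome on score: slope ~ 1 when calibrated
    x = scores - scores.mean()
    slope = float((x * (y - y.mean())).sum() / (x**2).sum())
    assert 0.8 <= slope <= 1.2
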