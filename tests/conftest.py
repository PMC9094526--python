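import numpy as np
import pandas as pd
import pytest

import divprop as dp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def confounded_run():
    """One matched confounded cohort shared by matching/balance tests."""
    spec = dp.confounded_cohort_spec(n=400, seed=7)
    pheno, features, truth = dp.generate_cohort(spec)
    y = pheno["diagnosis"].to_numpy()
    design = dp.encode_covariates(pheno)
    _, scores = dp.estimate_propensity(design, y, seed=7)
    s = pd.Series(scores, index=pheno["participant_id"])
    by_id = pheno.set_index("participant_id")["diagnosis"]
    pairs = dp.match_pairs(s[by_id[by_id == 1].index], s[by_id[by_id == 0].index])
    return {
        "pheno": pheno,
        "features": features,
        "truth": truth,
        "design": design,
        "labels": y,
        "scores": s,
        "pairs": pairs,
    }


def match_cohort(pheno, seed):
    """Propensity -> matching for an arbitrary phenotype table."""
    y = pheno["diagnosis"].to_numpy()
    design = dp.encode_covariates(pheno)
    _, scores = dp.estimate_propensity(design, y, seed=seed)
    s = pd.Series(scores, index=pheno["participant_id"])
    by_id = pheno.set_index("participant_id")["diagnosis"]
    pairs = dp.match_pairs(s[by_id[by_id == 1].index], s[by_id[by_id == 0].index])
    return design, s, pairs
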