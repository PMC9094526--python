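import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divprop.matching import MatchedPair
from divprop.sampling import (
    enumerate_draws,
    has_isolated_stratum,
    is_contiguous,
    ood_diversity,
    wd_diversity,
)
from divprop.stratification import stratify


def enumeration_wd(scores):
    diffs = [abs(a - b) for a, b in itertools.combinations(scores, 2)]
    return sum(diffs) / len(diffs)


def make_strat(n_pairs, q=10, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [
        MatchedPair(f"c{i}", f"t{i}", 0.0, float(s))
        for i, s in enumerate(rng.random(n_pairs))
    ]
    return stratify(pairs, q=q)


@pytest.mark.parametrize(
    "scores,expected",
    [([0.2, 0.4], 0.2), ([0.5, 0.5, 0.5], 0.0), ([0.1, 0.2, 0.7], 0.4)],
)
def test_wd_diversity_examples(scores, expected):
    assert wd_diversity(scores) == pytest.approx(expected)


def test_wd_diversity_matches_enumeration_on_random_inputs(rng):
    for n in (2, 3, 7, 20):
        scores = rng.random(n)
        assert wd_diversity(scores) == pytest.approx(enumeration_wd(scores))


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
def test_wd_diversity_enumeration_property(scores):
    assert wd_diversity(scores) == pytest.approx(enumeration_wd(scores), abs=1e-12)


@settings(max_examples=40, derandomize=True)
@given(
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
)
def test_ood_diversity_enumeration_property(train, holdout):
    expected = np.mean([abs(a - b) for a in train for b in holdout])
    assert ood_diversity(train, holdout) == pytest.approx(expected, abs=1e-12)
    assert ood_diversity(holdout, train) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "train,holdout,expected",
    [([0.5], [0.5], 0.0), ([0.0, 1.0], [0.5], 0.5), ([0.1, 0.3], [0.6, 0.9], 0.55)],
)
def test_ood_diversity_examples(train, holdout, expected):
    assert ood_diversity(train, holdout) == pytest.approx(expected)
    assert ood_diversity(holdout, train) == pytest.approx(expected)  # symmetric


def test_exhaustive_draw_count_is_252():
    strat = make_strat(40)
    assert len(enumerate_draws(strat, "all", 5)) == 252


def test_contiguous_windows_q10_r2_is_9():
    strat = make_strat(40)
    draws = enumerate_draws(strat, "contiguous", 2, n_draws=9)
    assert len(draws) == 9
    assert all(d.scheme == "contiguous" for d in draws)
    assert all(is_contiguous(d.train_strata) for d in draws)


def test_contiguous_augmented_to_twenty_draws():
    strat = make_strat(60)
    draws = enumerate_draws(strat, "contiguous", 2, n_draws=20)
    assert len(draws) == 20
    extra = [d for d in draws if d.scheme == "consecutive-extra"]
    assert len(extra) == 11
    n_train = round(strat.n_pairs * 2 / 10)
    for d in extra:
        idx = d.train_pair_indices
        assert len(idx) == n_train
        assert list(idx) == list(range(idx[0], idx[0] + n_train))  # consecutive run
    # no duplicated training sets across the whole scheme
    keys = {frozenset(d.train_pair_indices) for d in draws}
    assert len(keys) == 20


@pytest.mark.parametrize("q,r", [(5, 2), (8, 3), (10, 5), (12, 4)])
def test_draw_counts_match_brute_force(q, r):
    strat = make_strat(3 * q, q=q)
    all_draws = enumerate_draws(strat, "all", r)
    assert len(all_draws) == len(list(itertools.combinations(range(q), r)))
    contiguous = enumerate_draws(strat, "contiguous", r, n_draws=q - r + 1)
    assert len(contiguous) == q - r + 1
    diverse = enumerate_draws(strat, "diverse", r, n_draws=10**9)

    def brute_isolated(combo):
        members = set(combo)
        return any(s - 1 not in members and s + 1 not in members for s in members)

    brute_diverse = [
        c for c in itertools.combinations(range(q), r) if brute_isolated(c)
    ]
    assert len(diverse) == len(brute_diverse)
    assert {d.train_strata for d in diverse} == set(brute_diverse)
    # diverse sets are a subset of the non-contiguous sets
    assert all(not is_contiguous(d.train_strata) for d in diverse)


def test_diverse_draws_at_r_nine_need_an_isolated_terminal_stratum():
    # with 9 of 10 strata in training only two subsets leave a training
    # stratum isolated: the ones excluding a stratum adjacent to an end
    strat = make_strat(40)
    draws = enumerate_draws(strat, "diverse", 9, n_draws=100)
    assert {d.train_strata for d in draws} == {
        tuple(i for i in range(10) if i != 1),
        tuple(i for i in range(10) if i != 8),
    }
    assert not has_isolated_stratum((0, 1, 3, 4, 5))
    assert has_isolated_stratum((0, 1, 4))
    assert has_isolated_stratum((0, 9))


def test_diverse_ranking_non_increasing_in_wd():
    strat = make_strat(50)
    draws = enumerate_draws(strat, "diverse", 5, n_draws=20)
    wds = [d.wd for d in draws]
    assert wds == sorted(wds, reverse=True)


def test_random_draws_reproducible_and_train_fraction_respected():
    strat = make_strat(50)
    a = enumerate_draws(strat, "random", 5, n_draws=5, seed=11)
    b = enumerate_draws(strat, "random", 5, n_draws=5, seed=11)
    assert [d.train_pair_indices for d in a] == [d.train_pair_indices for d in b]
    assert all(len(d.train_pair_indices) == 25 for d in a)


def test_draws_keep_train_and_holdout_disjoint_and_balanced():
    strat = make_strat(40)
    for scheme in ("contiguous", "diverse", "random", "all"):
        for d in enumerate_draws(strat, scheme, 5, n_draws=5, seed=0):
            assert not set(d.train_pair_indices) & set(d.holdout_pair_indices)
            # pairs move as units, so case/control counts stay equal by design
            assert len(d.train_pair_indices) + len(d.holdout_pair_indices) == 40


def test_ood_computed_per_holdout_stratum():
    strat = make_strat(40)
    d = enumerate_draws(strat, "all", 5)[0]
    assert set(d.ood) == set(d.holdout_strata)
    assert all(v > 0 for v in d.ood.values())


def test_r_out_of_range_rejected():
    strat = make_strat(40)
    with pytest.raises(ValueError, match="r must be"):
        enumerate_draws(strat, "all", 1)
    with pytest.raises(ValueError, match="r must be"):
        enumerate_draws(strat, "all", 10)


def test_degenerate_score_lists_rejected():
    with pytest.raises(ValueError):
        wd_diversity([0.5])
    with pytest.raises(ValueError):
        ood_diversity([], [0.5])
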