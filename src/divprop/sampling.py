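"""Train/holdout draw enumeration and diversity indices.

A *draw* selects r of the q score-ordered strata for training; the rest are
held out. Three schemes are supported:

- contiguous: adjacent strata only (a narrow band of the propensity
  spectrum); when fewer windows exist than requested, extra draws of the
  same training fraction are formed from runs of consecutive matched pairs.
- diverse: stratum subsets containing at least one stratum isolated from
  the other training strata, ranked by the within-distribution diversity of
  the pooled training scores and truncated to the most diverse.
- random: seeded samples of matched pairs at the same training fraction,
  ignoring propensity scores (conventional cross-validation baseline).

An exhaustive mode enumerates every C(q, r) subset (252 at q=10, r=5).

Diversity indices: within-distribution (WD) diversity is the mean absolute
pairwise difference in propensity scores within a participant set,
2/(Nt(Nt-1)) * sum_{i<j} |pi_i - pi_j|; out-of-distribution (OOD) diversity
is the mean absolute difference over all training-by-holdout cross pairs,
1/(Nt*Ns) * sum_i sum_j |pi_i - pi_j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .stratification import Stratification

__all__ = [
    "Draw",
    "wd_diversity",
    "ood_diversity",
    "enumerate_draws",
    "is_contiguous",
    "has_isolated_stratum",
]


def wd_diversity(scores: Sequence[float]) -> float:
    """Mean absolute pairwise score difference within one participant set."""
    s = np.sort(np.asarray(scores, float).ravel())
    n = s.size
    if n < 2:
        raise ValueError("wd_diversity needs at least 2 scores")
    # sum_{i<j}(s_j - s_i) via the sorted-rank identity
    total = float(np.sum(s * (2 * np.arange(n) - n + 1)))
    return total / (n * (n - 1) / 2)


def ood_diversity(train_scores: Sequence[float], holdout_scores: Sequence[float]) -> float:
    """Mean absolute score difference over all train x holdout pairs."""
    a = np.asarray(train_scores, float).ravel()
    b = np.asarray(holdout_scores, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("ood_diversity needs non-empty score lists")
    return float(np.abs(a[:, None] - b[None, :]).mean())


def is_contiguous(stratum_indices: Sequence[int]) -> bool:
    """True iff the sorted stratum indices form an unbroken run."""
    idx = sorted(stratum_indices)
    return idx[-1] - idx[0] == len(idx) - 1


def has_isolated_stratum(stratum_indices: Sequence[int]) -> bool:
    """True iff some training stratum has no adjacent training stratum.

    This is the defining property of the diverse scheme: the training set
    must contain at least one stratum pulled away from the rest of the
    training block (e.g. {0,1,3,4,5} has a gap but no isolated stratum and
    does not qualify; {0,1,4} does via stratum 4). At r = q-1 no subset
    qualifies, so the diverse scheme is empty there.
    """
    members = set(stratum_indices)
    return any(s - 1 not in members and s + 1 not in members for s in members)


@dataclass
class Draw:
    """One train/holdout partition with its diversity bookkeeping."""

    scheme: str
    train_strata: tuple[int, ...] | None
    holdout_strata: tuple[int, ...] | None
    train_pair_indices: tuple[int, ...]
    holdout_pair_indices: tuple[int, ...]
    wd: float
    # holdout stratum index -> OOD diversity vs the training set; for draws
    # without stratum structure the single key -1 holds the pooled value
    ood: dict[int, float] = field(default_factory=dict)


def _pair_member_scores(strat: Stratification, scores: Mapping | None):
    """Per-pair [case score, control score] lists, in sorted-pair order."""
    out = []
    for p in strat.all_pairs():
        if scores is None:
            out.append((p.mean_score, p.mean_score))
        else:
            out.append((float(scores[p.case_id]), float(scores[p.control_id])))
    return out


def _participant_scores(pair_scores, pair_indices) -> np.ndarray:
    return np.array([s for i in pair_indices for s in pair_scores[i]])


def _make_draw(scheme, strat, pair_scores, train_strata, stratum_ranges) -> Draw:
    train_strata = tuple(sorted(train_strata))
    holdout_strata = tuple(i for i in range(strat.q) if i not in train_strata)
    train_idx = tuple(i for s in train_strata for i in stratum_ranges[s])
    holdout_idx = tuple(i for s in holdout_strata for i in stratum_ranges[s])
    train_scores = _participant_scores(pair_scores, train_idx)
    ood = {
        s: ood_diversity(train_scores, _participant_scores(pair_scores, stratum_ranges[s]))
        for s in holdout_strata
    }
    return Draw(
        scheme=scheme,
        train_strata=train_strata,
        holdout_strata=holdout_strata,
        train_pair_indices=train_idx,
        holdout_pair_indices=holdout_idx,
        wd=wd_diversity(train_scores),
        ood=ood,
    )


def _pair_level_draw(scheme, pair_scores, n_pairs, train_idx) -> Draw:
    train_idx = tuple(train_idx)
    holdout_idx = tuple(i for i in range(n_pairs) if i not in set(train_idx))
    train_scores = _participant_scores(pair_scores, train_idx)
    ood = {-1: ood_diversity(train_scores, _participant_scores(pair_scores, holdout_idx))}
    return Draw(
        scheme=scheme,
        train_strata=None,
        holdout_strata=None,
        train_pair_indices=train_idx,
        holdout_pair_indices=holdout_idx,
        wd=wd_diversity(train_scores),
        ood=ood,
    )


def enumerate_draws(
    strat: Stratification,
    scheme: str,
    r: int,
    n_draws: int = 20,
    seed: int | None = None,
    scores: Mapping | None = None,
) -> list[Draw]:
    """Enumerate train/holdout draws under one sampling scheme.

    Parameters
    ----------
    strat
        Score-ordered stratification of matched pairs.
    scheme
        ``"contiguous"``, ``"diverse"``, ``"random"``, or ``"all"``
        (exhaustive enumeration of every r-subset).
    r
        Number of training strata, 2 <= r <= q-1.
    n_draws
        Target number of draws for the contiguous (after augmentation),
        diverse (truncation) and random schemes.
    seed
        Seed for the random scheme.
    scores
        Optional mapping participant id -> propensity score. When omitted,
        each pair contributes its pair-mean score for both members, which
        leaves the diversity ordering of draws essentially unchanged.
    """
    q = strat.q
    if not (2 <= r <= q - 1):
        raise ValueError(f"r must be in [2, {q - 1}], got {r}")
    pair_scores = _pair_member_scores(strat, scores)
    n_pairs = strat.n_pairs
    sizes = [len(s) for s in strat.strata]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    stratum_ranges = [range(offsets[s], offsets[s + 1]) for s in range(q)]

    if scheme == "contiguous":
        draws = [
            _make_draw(scheme, strat, pair_scores, range(k, k + r), stratum_ranges)
            for k in range(q - r + 1)
        ]
        if len(draws) < n_draws:
            draws += _consecutive_extra(
                pair_scores, n_pairs, r, q, n_draws - len(draws), draws
            )
        return draws

    if scheme == "diverse":
        candidates = [
            _make_draw(scheme, strat, pair_scores, combo, stratum_ranges)
            for combo in combinations(range(q), r)
            if has_isolated_stratum(combo)
        ]
        candidates.sort(key=lambda d: (-d.wd, d.train_strata))
        return candidates[:n_draws]

    if scheme == "random":
        rng = np.random.default_rng(seed)
        n_train = int(round(n_pairs * r / q))
        return [
            _pair_level_draw(
                scheme, pair_scores, n_pairs,
                sorted(rng.choice(n_pairs, size=n_train, replace=False).tolist()),
            )
            for _ in range(n_draws)
        ]

    if scheme == "all":
        return [
            _make_draw(scheme, strat, pair_scores, combo, stratum_ranges)
            for combo in combinations(range(q), r)
        ]

    raise ValueError(f"unknown scheme {scheme!r}")


def _consecutive_extra(pair_scores, n_pairs, r, q, n_extra, existing) -> list[Draw]:
    """Extra draws from runs of consecutive pairs at the same training fraction.

    Window starts are evenly spaced over the sorted pair list and draws
    duplicating an existing training set are dropped.
    """
    n_train = int(round(n_pairs * r / q))
    if n_train < 1 or n_train >= n_pairs:
        return []
    seen = {frozenset(d.train_pair_indices) for d in existing}
    draws: list[Draw] = []
    # oversample candidate starts; dedup trims back down
    starts = np.unique(
        np.round(np.linspace(0, n_pairs - n_train, max(2 * n_extra, 2))).astype(int)
    )
    for start in starts:
        train = tuple(range(start, start + n_train))
        key = frozenset(train)
        if key in seen:
            continue
        seen.add(key)
        draws.append(_pair_level_draw("consecutive-extra", pair_scores, n_pairs, train))
        if len(draws) == n_extra:
            break
    return draws
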