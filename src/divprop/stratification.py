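"""Score-ordered stratification of matched pairs.

Matched pairs are ranked by their pair-mean propensity score and chunked
into q contiguous, equally sized strata (default q = 10, i.e. deciles).
When the pair count is not divisible by q the remainder goes to the
lowest-score strata by default. Ties in the pair-mean score are broken by
(case_id, control_id) so the partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matching import MatchedPair

__all__ = ["Stratification", "stratify", "chunk_sizes"]


def chunk_sizes(n: int, k: int, remainder_to_front: bool = True) -> list[int]:
    """Sizes of k near-equal contiguous chunks of n items (differ by <= 1)."""
    base, rem = divmod(n, k)
    if remainder_to_front:
        return [base + 1] * rem + [base] * (k - rem)
    return [base] * (k - rem) + [base + 1] * rem


@dataclass
class Stratification:
    """q ordered strata of matched pairs, ascending in pair-mean score."""

    strata: list[list[MatchedPair]]

    @property
    def q(self) -> int:
        return len(self.strata)

    @property
    def n_pairs(self) -> int:
        return sum(len(s) for s in self.strata)

    def all_pairs(self) -> list[MatchedPair]:
        return [p for stratum in self.strata for p in stratum]

    def stratum_scores(self, idx: int) -> list[float]:
        """Individual propensity-derived pair-mean scores of one stratum.

        Each pair contributes its pair-mean score twice (once per member),
        matching the participant-level score lists used by the diversity
        indices when only pair summaries are carried forward.
        """
        return [p.mean_score for p in self.strata[idx]]


def stratify(
    pairs: list[MatchedPair], q: int = 10, remainder_to_front: bool = True
) -> Stratification:
    """Partition matched pairs into q score-ordered equally sized strata."""
    if q < 2:
        raise ValueError("q must be at least 2")
    if len(pairs) < q:
        raise ValueError(f"need at least q={q} pairs, got {len(pairs)}")
    ordered = sorted(pairs, key=lambda p: (p.mean_score, str(p.case_id), str(p.control_id)))
    sizes = chunk_sizes(len(ordered), q, remainder_to_front)
    strata, start = [], 0
    for size in sizes:
        strata.append(ordered[start : start + size])
        start += size
    return Stratification(strata)
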