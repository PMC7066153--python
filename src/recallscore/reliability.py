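"""Human-rater agreement and transcription fidelity (word error rate).

Each recall response is rated for accuracy on a 0-6 scale by several
raters (three to seven in the study design); the mean rating per response
is the gold standard the automated model is trained to predict.  Agreement
is summarized two ways: each rater against the mean of the *other* raters
(leave-one-out gold), and all pairwise rater-rater correlations.

Transcript fidelity is measured with the word error rate (WER): the
substitution/deletion/insertion counts of a minimum unit-cost alignment,
divided by the reference length.  Corpus-level WER pools edit counts over
reference lengths (not a mean of per-file rates).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .model import ConstantInputError, pearson_r
from .textprep import TokenSequence

__all__ = [
    "RatingSet",
    "AlignmentCounts",
    "gold_standard",
    "rater_vs_rest",
    "pairwise_interrater",
    "word_error_rate",
    "corpus_wer",
]

logger = logging.getLogger(__name__)

RATING_MIN, RATING_MAX = 0.0, 6.0


@dataclass
class RatingSet:
    """Multi-rater 0-6 ratings keyed by (response_id, rater_id)."""

    ratings: dict[tuple[Hashable, Hashable], float] = field(default_factory=dict)

    def add(self, response_id: Hashable, rater_id: Hashable, rating: float) -> None:
        rating = float(rating)
        if not RATING_MIN <= rating <= RATING_MAX:
            raise ValueError(
                f"rating {rating} for response {response_id!r} outside [0, 6]"
            )
        key = (response_id, rater_id)
        if key in self.ratings:
            raise ValueError(f"duplicate rating for {key!r}")
        self.ratings[key] = rating

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[Hashable, Hashable, float]]
    ) -> "RatingSet":
        rs = cls()
        for response_id, rater_id, rating in records:
            rs.add(response_id, rater_id, rating)
        return rs

    @property
    def response_ids(self) -> list[Hashable]:
        seen = dict.fromkeys(rid for rid, _ in self.ratings)
        return list(seen)

    @property
    def rater_ids(self) -> list[Hashable]:
        seen = dict.fromkeys(rater for _, rater in self.ratings)
        return list(seen)

    def ratings_for(self, response_id: Hashable) -> dict[Hashable, float]:
        return {
            rater: value
            for (rid, rater), value in self.ratings.items()
            if rid == response_id
        }

    def by_rater(self, rater_id: Hashable) -> dict[Hashable, float]:
        return {
            rid: value
            for (rid, rater), value in self.ratings.items()
            if rater == rater_id
        }


def gold_standard(ratings: RatingSet) -> dict[Hashable, float]:
    """Mean rating per response — the gold standard the model predicts."""
    sums: dict[Hashable, float] = {}
    counts: dict[Hashable, int] = {}
    for (rid, _), value in ratings.ratings.items():
        sums[rid] = sums.get(rid, 0.0) + value
        counts[rid] = counts.get(rid, 0) + 1
    return {rid: sums[rid] / counts[rid] for rid in sums}


def rater_vs_rest(
    ratings: RatingSet, rater_id: Hashable, include_self: bool = False
) -> float:
    """Correlation of one rater with the mean of the remaining raters.

    With ``include_self`` the comparison gold includes the rater's own
    rating (the non-leave-one-out convention); the default leaves it out.
    Requires at least three responses that the rater shares with at least
    one other rater.
    """
    own = ratings.by_rater(rater_id)
    xs: list[float] = []
    ys: list[float] = []
    for rid, value in own.items():
        others = ratings.ratings_for(rid)
        if not include_self:
            others = {r: v for r, v in others.items() if r != rater_id}
        if not others:
            continue
        xs.append(value)
        ys.append(float(np.mean(list(others.values()))))
    try:
        return pearson_r(xs, ys)
    except ValueError as exc:
        raise ConstantInputError(
            f"rater {rater_id!r}: insufficient overlap or degenerate ratings ({exc})"
        ) from exc


def pairwise_interrater(
    ratings: RatingSet, min_overlap: int = 3
) -> tuple[dict[tuple[Hashable, Hashable], float], float]:
    """Pearson correlation for every rater pair on jointly rated responses.

    Pairs sharing fewer than ``min_overlap`` responses (or with constant
    ratings) are omitted and logged.  Returns the per-pair map and the
    unweighted mean across reported pairs.
    """
    by_rater = {rater: ratings.by_rater(rater) for rater in ratings.rater_ids}
    pairs: dict[tuple[Hashable, Hashable], float] = {}
    for ra, rb in itertools.combinations(by_rater, 2):
        shared = sorted(set(by_rater[ra]) & set(by_rater[rb]), key=repr)
        if len(shared) < min_overlap:
            logger.warning(
                "rater pair (%r, %r) omitted: only %d jointly rated responses",
                ra, rb, len(shared),
            )
            continue
        try:
            pairs[(ra, rb)] = pearson_r(
                [by_rater[ra][rid] for rid in shared],
                [by_rater[rb][rid] for rid in shared],
            )
        except ConstantInputError:
            logger.warning("rater pair (%r, %r) omitted: constant ratings", ra, rb)
    mean = float(np.mean(list(pairs.values()))) if pairs else float("nan")
    return pairs, mean


@dataclass(frozen=True)
class AlignmentCounts:
    """Edit operations of a minimum-cost transcript alignment."""

    substitutions: int
    deletions: int
    insertions: int
    ref_length: int

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.deletions + self.insertions


def _tokens(seq: TokenSequence | Sequence[str]) -> list[str]:
    return list(seq.tokens) if isinstance(seq, TokenSequence) else list(seq)


def word_error_rate(
    reference: TokenSequence | Sequence[str],
    hypothesis: TokenSequence | Sequence[str],
) -> tuple[AlignmentCounts, float]:
    """WER of a hypothesis transcript against a reference.

    Dynamic-programming Levenshtein alignment with unit costs; among
    tied optimal alignments the backtrace prefers substitution over
    insertion over deletion (only S+D+I is contractual).  The rate is
    (S+D+I)/len(reference); NaN when the reference is empty but the
    hypothesis is not (the counts are still returned, all insertions).
    """
    ref = _tokens(reference)
    hyp = _tokens(hypothesis)
    n, m = len(ref), len(hyp)

    # dist[i][j] = edit distance between ref[:i] and hyp[:j]
    dist = np.zeros((n + 1, m + 1), dtype=int)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            ins = dist[i, j - 1] + 1
            dele = dist[i - 1, j] + 1
            dist[i, j] = min(sub, ins, dele)

    s = d = ins_count = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + (
            ref[i - 1] != hyp[j - 1]
        ):
            s += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif j > 0 and dist[i, j] == dist[i, j - 1] + 1:
            ins_count += 1
            j -= 1
        else:
            d += 1
            i -= 1

    counts = AlignmentCounts(
        substitutions=int(s), deletions=int(d), insertions=int(ins_count), ref_length=n
    )
    if n == 0:
        rate = 0.0 if m == 0 else float("nan")
    else:
        rate = counts.total_errors / n
    return counts, rate


def corpus_wer(
    pairs: Iterable[
        tuple[TokenSequence | Sequence[str], TokenSequence | Sequence[str]]
    ],
) -> float:
    """Corpus-level WER: pooled edit counts over pooled reference length."""
    total_errors = 0
    total_ref = 0
    for reference, hypothesis in pairs:
        counts, _ = word_error_rate(reference, hypothesis)
        total_errors += counts.total_errors
        total_ref += counts.ref_length
    if total_ref == 0:
        raise ValueError("corpus WER needs at least one non-empty reference")
    return total_errors / total_ref
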