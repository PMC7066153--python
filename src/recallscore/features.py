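"""Similarity features between a story prompt and a recall transcript.

Two predictors drive the scoring model:

* ``common_types`` — the number of distinct word types shared between
  prompt and recall, a surface measure of how much of the story's
  vocabulary was reproduced verbatim.
* ``wmd`` — the Word Mover's Distance between the prompt and the recall in
  an embedding space: the minimum cumulative embedding-space distance
  needed to transport the recall's normalized bag-of-words (nBOW) mass
  onto the prompt's.  WMD credits paraphrase ("dad" for "father") that the
  surface count misses.

The transport problem is solved exactly as a dense linear program; only
the optimal objective value is contractual (optimal plans may be
non-unique).  Out-of-vocabulary tokens are dropped before nBOW
normalization; a recall with no in-vocabulary tokens is *unscorable* and
carries a missing (NaN) distance rather than raising through the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .embeddings import EmbeddingSpace, lookup
from .textprep import TokenSequence, word_types

__all__ = [
    "MISSING",
    "UnscorableResponseError",
    "NBowDistribution",
    "FeatureVector",
    "common_types",
    "nbow",
    "wmd",
    "word_centroid_distance",
    "extract_features",
]

#: Marker for a distance that could not be computed (unscorable response).
MISSING = float("nan")


class UnscorableResponseError(ValueError):
    """A response has no in-vocabulary token, so no nBOW distribution exists.

    Distinct from file-format errors: it signals a legitimate but
    unscorable response (e.g. silence, or speech entirely outside the
    embedding vocabulary).
    """


@dataclass(frozen=True)
class NBowDistribution:
    """Normalized bag-of-words: a probability distribution over word types.

    ``weights[i]`` is the relative frequency of ``words[i]`` among the
    document's in-vocabulary tokens.
    """

    words: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.words) != len(self.weights):
            raise ValueError("words and weights must align")
        if len(set(self.words)) != len(self.words):
            raise ValueError("nBOW words must be distinct")
        if np.any(self.weights <= 0):
            raise ValueError("nBOW weights must be strictly positive")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("nBOW weights must sum to 1")


@dataclass(frozen=True)
class FeatureVector:
    """The per-response predictors fed to the scoring model."""

    common_types: int
    wmd: float  # NaN when the response is unscorable
    n_tokens: int
    n_oov: int = 0

    @property
    def wmd_missing(self) -> bool:
        return math.isnan(self.wmd)


def common_types(prompt: TokenSequence, response: TokenSequence) -> int:
    """Count distinct word types shared between prompt and response."""
    return len(word_types(prompt) & word_types(response))


def nbow(tokens: TokenSequence, space: EmbeddingSpace) -> NBowDistribution:
    """Build the nBOW distribution of a document over the embedding vocab.

    Out-of-vocabulary tokens are dropped before normalization.  Raises
    :class:`UnscorableResponseError` if no token is in vocabulary.
    """
    in_vocab, _ = lookup(space, tokens)
    if not in_vocab:
        raise UnscorableResponseError(
            "no in-vocabulary token; cannot form an nBOW distribution"
        )
    words = sorted(set(in_vocab))
    counts = np.array([in_vocab.count(w) for w in words], dtype=float)
    return NBowDistribution(tuple(words), counts / counts.sum())


def _cost_matrix(
    a: NBowDistribution,
    b: NBowDistribution,
    space: EmbeddingSpace,
    metric: str,
) -> np.ndarray:
    xa = space.matrix(a.words)
    xb = space.matrix(b.words)
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported WMD cost metric {metric!r}")
    return cdist(xa, xb, metric=metric)


def wmd(
    prompt_nbow: NBowDistribution,
    response_nbow: NBowDistribution,
    space: EmbeddingSpace,
    metric: str = "euclidean",
) -> float:
    """Word Mover's Distance between two nBOW distributions.

    Solves the transportation linear program

        min  sum_ij T_ij * c_ij
        s.t. sum_j T_ij = w_i,   sum_i T_ij = w'_j,   T_ij >= 0

    with ``c_ij`` the pairwise embedding distance, and returns the optimal
    objective.  Symmetric in its two document arguments; zero iff the
    distributions coincide.
    """
    cost = _cost_matrix(prompt_nbow, response_nbow, space, metric)
    n, m = cost.shape
    if n == 1 and m == 1:
        return float(cost[0, 0])

    # Equality constraints: n row marginals + m column marginals.  One
    # constraint is redundant (both sides sum to 1); HiGHS copes, but we
    # drop the last column constraint to keep the system full-rank.
    a_eq = np.zeros((n + m - 1, n * m))
    b_eq = np.zeros(n + m - 1)
    for i in range(n):
        a_eq[i, i * m : (i + 1) * m] = 1.0
        b_eq[i] = prompt_nbow.weights[i]
    for j in range(m - 1):
        a_eq[n + j, j::m] = 1.0
        b_eq[n + j] = response_nbow.weights[j]

    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - feasible by construction
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(float(res.fun), 0.0)


def word_centroid_distance(
    prompt_nbow: NBowDistribution,
    response_nbow: NBowDistribution,
    space: EmbeddingSpace,
) -> float:
    """Distance between the weighted centroid vectors of two documents.

    This is the classic relaxation of the transport problem: moving all
    mass between the centroids can never cost more than the optimal plan,
    so it lower-bounds :func:`wmd` (with the Euclidean cost).
    """
    ca = prompt_nbow.weights @ space.matrix(prompt_nbow.words)
    cb = response_nbow.weights @ space.matrix(response_nbow.words)
    return float(np.linalg.norm(ca - cb))


def extract_features(
    prompt: TokenSequence,
    response: TokenSequence,
    space: EmbeddingSpace,
    metric: str = "euclidean",
    stopwords: frozenset[str] | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one prompt/response pair.

    ``stopwords``, when given, are removed from both documents before
    either feature is computed (off by default).  An unscorable response
    yields ``wmd = NaN``; the prompt itself must have at least one
    in-vocabulary token.
    """
    if stopwords:
        prompt = TokenSequence(
            tuple(t for t in prompt.tokens if t not in stopwords), prompt.source_text
        )
        response = TokenSequence(
            tuple(t for t in response.tokens if t not in stopwords),
            response.source_text,
        )
    prompt_dist = nbow(prompt, space)  # raises if the prompt is unscorable
    _, oov = lookup(space, response)
    try:
        response_dist = nbow(response, space)
        distance = wmd(prompt_dist, response_dist, space, metric=metric)
    except UnscorableResponseError:
        distance = MISSING
    return FeatureVector(
        common_types=common_types(prompt, response),
        wmd=distance,
        n_tokens=len(response),
        n_oov=len(oov),
    )
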