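"""Word embedding spaces in word2vec text format.

Semantic distance between a recall and its prompt is computed in a
pre-trained word vector space (the study design assumes a 300-dimensional
word2vec space; any dimensionality works).  Only the plain-text word2vec
export dialect is supported: a ``<vocab_size> <dim>`` header line followed
by one ``word v1 v2 ... v_dim`` line per word.  Matching is exact string
match on preprocessed (case-folded) tokens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .textprep import TokenSequence

__all__ = [
    "EmbeddingFormatError",
    "EmbeddingSpace",
    "read_word2vec_text",
    "write_word2vec_text",
    "lookup",
]


class EmbeddingFormatError(ValueError):
    """Raised when an embedding file violates the word2vec text format."""


@dataclass
class EmbeddingSpace:
    """A vocabulary-to-vector map with a fixed dimensionality."""

    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"embedding dimension must be >= 1, got {self.dim}")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector for {word!r} has shape {vec.shape}, expected ({self.dim},)"
                )

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def vocab(self) -> frozenset[str]:
        return frozenset(self.vectors)

    def matrix(self, words: Iterable[str]) -> np.ndarray:
        """Stack the vectors for ``words`` into a ``(len(words), dim)`` array."""
        return np.array([self.vectors[w] for w in words], dtype=float)


def read_word2vec_text(path: str | os.PathLike[str]) -> EmbeddingSpace:
    """Read an embedding space from a word2vec-format text file.

    Words are case-folded on read so they match preprocessed tokens.
    Malformed headers, rows with the wrong number of values, non-numeric
    values and duplicate words raise :class:`EmbeddingFormatError` naming
    the offending line.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise EmbeddingFormatError(
                f"{path}: line 1: expected header '<vocab_size> <dim>', got {header!r}"
            )
        try:
            vocab_size, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise EmbeddingFormatError(
                f"{path}: line 1: non-integer header fields in {header!r}"
            ) from None
        if vocab_size < 0 or dim < 1:
            raise EmbeddingFormatError(
                f"{path}: line 1: invalid header values {vocab_size} {dim}"
            )

        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            word = fields[0].casefold()
            if len(fields) - 1 != dim:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: expected {dim} values for "
                    f"{word!r}, got {len(fields) - 1}"
                )
            if word in vectors:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: duplicate word {word!r}"
                )
            try:
                vectors[word] = np.array([float(x) for x in fields[1:]], dtype=float)
            except ValueError:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: non-numeric vector value for {word!r}"
                ) from None

    if len(vectors) != vocab_size:
        raise EmbeddingFormatError(
            f"{path}: header declares {vocab_size} words but file contains {len(vectors)}"
        )
    return EmbeddingSpace(dim=dim, vectors=vectors)


def write_word2vec_text(
    space: EmbeddingSpace, path: str | os.PathLike[str], fmt: str = "%.8g"
) -> None:
    """Write an embedding space in word2vec text format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for word, vec in space.vectors.items():
            values = " ".join(fmt % x for x in vec)
            fh.write(f"{word} {values}\n")


def lookup(
    space: EmbeddingSpace, tokens: TokenSequence | Iterable[str]
) -> tuple[list[str], list[str]]:
    """Partition tokens into in-vocabulary and out-of-vocabulary lists.

    Multiplicity and order are preserved; the concatenation of both parts
    is a permutation-free re-partition of the input.
    """
    in_vocab: list[str] = []
    out_of_vocab: list[str] = []
    for token in tokens:
        (in_vocab if token in space else out_of_vocab).append(token)
    return in_vocab, out_of_vocab
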