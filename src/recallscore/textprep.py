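"""Normalization of story prompts and recall transcripts into token sequences.

Spoken-language transcripts carry casing, punctuation and filled pauses
("uh", "um") that are irrelevant to recall content.  Scoring therefore
operates on a canonical token sequence: case-folded words with punctuation
stripped and hesitation markers removed.  No stemming, stop-word removal or
spelling correction happens here — the downstream features are deliberately
computed on surface word forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Iterator

#: Filled-pause markers removed during preprocessing.  Transcription
#: conventions vary; this set covers the common English renderings and can be
#: overridden per call or through the pipeline configuration.
DEFAULT_HESITATION_LEXICON: FrozenSet[str] = frozenset(
    {"uh", "um", "er", "ah", "eh", "hm", "hmm", "mhm", "uh-huh", "um-hum"}
)

# A word is a run of letters/digits, optionally joined by apostrophes
# ("don't", "o'clock").  Underscore is excluded from \w; hyphens and all
# other punctuation act as separators.
_WORD_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)

# Typographic apostrophes are normalized so "don’t" == "don't".
_APOSTROPHE_MAP = str.maketrans({"’": "'", "‘": "'"})

# Leading/trailing non-word characters of a whitespace chunk (used when
# matching multi-part hesitation markers such as "uh-huh,").
_EDGE_PUNCT_RE = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered, preprocessed sequence of word tokens.

    Parameters
    ----------
    tokens
        Lowercase word tokens in surface order.  Tokens contain no
        whitespace and no punctuation other than intra-word apostrophes.
    source_text
        The raw string the tokens were derived from (kept for diagnostics).
    """

    tokens: tuple[str, ...]
    source_text: str = field(default="", compare=False)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)

    def text(self) -> str:
        """The tokens re-joined with single spaces."""
        return " ".join(self.tokens)


def preprocess(
    raw_text: str,
    hesitation_lexicon: Iterable[str] = DEFAULT_HESITATION_LEXICON,
) -> TokenSequence:
    """Normalize raw prompt or transcript text into a :class:`TokenSequence`.

    The text is Unicode case-folded, punctuation is stripped (apostrophes
    between letters survive; hyphens split words), and any token matching
    the hesitation lexicon is dropped.  Hesitation entries that themselves
    contain hyphens ("uh-huh") are matched against whole whitespace chunks
    before splitting.  Empty input yields an empty sequence.
    """
    lexicon = {entry.casefold() for entry in hesitation_lexicon}
    text = raw_text.casefold().translate(_APOSTROPHE_MAP)
    tokens: list[str] = []
    for chunk in text.split():
        core = _EDGE_PUNCT_RE.sub("", chunk)
        if core in lexicon:
            continue
        for token in _WORD_RE.findall(chunk):
            if token not in lexicon:
                tokens.append(token)
    return TokenSequence(tuple(tokens), raw_text)


def word_types(seq: TokenSequence) -> frozenset[str]:
    """The set of distinct word types in a sequence (each counted once)."""
    return frozenset(seq.tokens)
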