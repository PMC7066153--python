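"""Pipeline configuration: tokenization policy and scoring options.

The configuration is a small JSON document; a SHA-1 fingerprint of its
canonical form is logged and stored in persisted models so every score is
traceable to the exact preprocessing policy that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

from .textprep import DEFAULT_HESITATION_LEXICON

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Options shared across the scoring pipeline.

    ``remove_stopwords`` filters a standard English stop-word list out of
    both prompt and response before feature computation (off by default:
    the scoring method's preprocessing is lowercasing, punctuation and
    hesitation-marker removal only).  ``wer_remove_hesitations`` controls
    whether filled pauses are stripped before word-error-rate alignment
    (off by default — ASR filled-pause output is a real error source).
    """

    hesitation_lexicon: tuple[str, ...] = tuple(sorted(DEFAULT_HESITATION_LEXICON))
    remove_stopwords: bool = False
    wmd_metric: str = "euclidean"  # or "cosine"
    clip_predictions: bool = False
    wer_remove_hesitations: bool = False

    def __post_init__(self) -> None:
        if self.wmd_metric not in ("euclidean", "cosine"):
            raise ValueError(f"unsupported wmd_metric {self.wmd_metric!r}")

    def stopwords(self) -> frozenset[str]:
        if not self.remove_stopwords:
            return frozenset()
        from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

        return frozenset(ENGLISH_STOP_WORDS)

    def fingerprint(self) -> str:
        """Stable SHA-1 digest of the canonical configuration."""
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(canonical.encode()).hexdigest()[:12]


def load_config(path: str | os.PathLike[str]) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON file.

    The hesitation lexicon may be given as a JSON array; unknown keys are
    rejected so typos fail loudly.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "hesitation_lexicon" in payload:
        payload["hesitation_lexicon"] = tuple(sorted(payload["hesitation_lexicon"]))
    return PipelineConfig(**payload)
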