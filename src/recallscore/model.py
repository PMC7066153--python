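"""Linear scoring model emulating expert 0-6 recall ratings.

An ordinary least squares regression maps the two similarity features
(common word types and Word Mover's Distance) to the gold-standard human
rating.  Performance is assessed with k-fold cross-validation: the Pearson
correlation between held-out predictions and the gold ratings, pooled over
all folds, is the headline metric, with the per-fold correlations reported
as a range check.

Responses with a missing (unscorable) WMD are excluded from fitting and
receive missing predictions — they are never silently dropped from the
bookkeeping, only from the arithmetic.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .features import FeatureVector

__all__ = [
    "SingularDesignError",
    "ConstantInputError",
    "ScoringModel",
    "CVReport",
    "fit_ols",
    "predict",
    "cross_validate",
    "pearson_r",
]


class SingularDesignError(ValueError):
    """The feature design matrix is rank-deficient (e.g. identical rows)."""


class ConstantInputError(ValueError):
    """A correlation was requested on a constant (zero-variance) input."""


@dataclass(frozen=True)
class ScoringModel:
    """Intercept + two coefficients mapping features to a 0-6 rating."""

    intercept: float
    coef_common_types: float
    coef_wmd: float
    metadata: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_common_types": self.coef_common_types,
            "coef_wmd": self.coef_wmd,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoringModel":
        return cls(
            intercept=float(payload["intercept"]),
            coef_common_types=float(payload["coef_common_types"]),
            coef_wmd=float(payload["coef_wmd"]),
            metadata=dict(payload.get("metadata", {})),
        )

    def save(self, path: str | os.PathLike[str]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike[str]) -> "ScoringModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CVReport:
    """Cross-validation outcome on held-out predictions only."""

    fold_assignments: dict[Hashable, int]
    per_fold_r: list[float]
    pooled_r: float
    r_squared: float  # pooled_r ** 2 (pooled convention)
    predictions: dict[Hashable, float]


def _design(features: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and a validity mask (rows with non-missing WMD)."""
    x = np.array([[fv.common_types, fv.wmd] for fv in features], dtype=float)
    valid = ~np.isnan(x[:, 1])
    return x, valid


def fit_ols(
    features: Sequence[FeatureVector], gold: Sequence[float]
) -> ScoringModel:
    """Fit the two-feature OLS model on responses with complete features.

    Requires at least three scorable responses and a full-rank design;
    raises :class:`SingularDesignError` otherwise.  The number of excluded
    (unscorable) responses is recorded in the model metadata.
    """
    if len(features) != len(gold):
        raise ValueError("features and gold ratings must align")
    x, valid = _design(features)
    y = np.asarray(gold, dtype=float)
    n_excluded = int((~valid).sum())
    x, y = x[valid], y[valid]
    if len(x) < 3:
        raise ValueError(f"need >=3 scorable responses to fit, got {len(x)}")
    augmented = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(augmented) < 3:
        raise SingularDesignError("feature design matrix is rank-deficient")
    reg = LinearRegression().fit(x, y)
    return ScoringModel(
        intercept=float(reg.intercept_),
        coef_common_types=float(reg.coef_[0]),
        coef_wmd=float(reg.coef_[1]),
        metadata={"n_fit": int(len(x)), "n_excluded_missing_wmd": n_excluded},
    )


def predict(
    model: ScoringModel, features: FeatureVector, clip: bool = False
) -> float:
    """Predicted rating for one response; NaN when the WMD is missing.

    With ``clip`` the raw prediction is clamped to the 0-6 rating scale.
    """
    if features.wmd_missing:
        return float("nan")
    raw = (
        model.intercept
        + model.coef_common_types * features.common_types
        + model.coef_wmd * features.wmd
    )
    if clip:
        raw = min(max(raw, 0.0), 6.0)
    return float(raw)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; rejects constant inputs explicitly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def cross_validate(
    features: Sequence[FeatureVector],
    gold: Sequence[float],
    response_ids: Sequence[Hashable] | None = None,
    k: int = 5,
    seed: int = 0,
    clip: bool = False,
) -> CVReport:
    """k-fold cross-validation of the scoring model.

    Responses are shuffled into ``k`` folds (fixed ``seed``); each fold is
    predicted by a model fitted on the other k-1 folds, so every response
    is held out exactly once.  ``pooled_r`` is the Pearson correlation of
    the concatenated held-out predictions against the gold ratings
    (unscorable responses excluded); ``per_fold_r`` holds the fold-wise
    correlations (NaN where a fold is too small or degenerate).
    """
    n = len(features)
    if len(gold) != n:
        raise ValueError("features and gold ratings must align")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} responses, got {n}")
    if response_ids is None:
        response_ids = list(range(n))
    elif len(response_ids) != n:
        raise ValueError("response_ids must align with features")
    if len(set(response_ids)) != n:
        raise ValueError("response_ids must be unique")

    features = list(features)
    y = np.asarray(gold, dtype=float)
    fold_assignments: dict[Hashable, int] = {}
    predictions: dict[Hashable, float] = {}
    per_fold_r: list[float] = []
    pooled_pred: list[float] = []
    pooled_gold: list[float] = []

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        fitted = fit_ols([features[i] for i in train_idx], y[train_idx])
        fold_pred: list[float] = []
        fold_gold: list[float] = []
        for i in test_idx:
            rid = response_ids[i]
            fold_assignments[rid] = fold
            p = predict(fitted, features[i], clip=clip)
            predictions[rid] = p
            if not math.isnan(p):
                fold_pred.append(p)
                fold_gold.append(float(y[i]))
                pooled_pred.append(p)
                pooled_gold.append(float(y[i]))
        try:
            per_fold_r.append(pearson_r(fold_pred, fold_gold))
        except (ValueError, ConstantInputError):
            per_fold_r.append(float("nan"))

    pooled = pearson_r(pooled_pred, pooled_gold)
    return CVReport(
        fold_assignments=fold_assignments,
        per_fold_r=per_fold_r,
        pooled_r=pooled,
        r_squared=pooled**2,
        predictions=predictions,
    )
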