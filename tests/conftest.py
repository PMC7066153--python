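"""Shared fixtures: tiny embedding spaces and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from recallscore.embeddings import EmbeddingSpace
from recallscore.synthetic import SimulationConfig, simulate_study


@pytest.fixture
def line_space() -> EmbeddingSpace:
    """1-D space with words a=0, b=10, c=1, d=9 (hand-checkable costs)."""
    return EmbeddingSpace(
        dim=1,
        vectors={
            "a": np.array([0.0]),
            "b": np.array([10.0]),
            "c": np.array([1.0]),
            "d": np.array([9.0]),
        },
    )


@pytest.fixture
def toy_space() -> EmbeddingSpace:
    """Small 3-D space with fixed, irregular vectors."""
    rng = np.random.default_rng(7)
    words = ["girl", "balloon", "party", "red", "cake", "dad", "father", "ran"]
    return EmbeddingSpace(
        dim=3, vectors={w: rng.normal(size=3) for w in words}
    )


def random_space(rng: np.random.Generator, n_words: int, dim: int = 3) -> EmbeddingSpace:
    words = [f"w{i}" for i in range(n_words)]
    return EmbeddingSpace(
        dim=dim, vectors={w: rng.normal(size=dim) for w in words}
    )


@pytest.fixture(scope="session")
def small_study():
    """A reproducible ~90-trial synthetic study shared across tests."""
    cfg = SimulationConfig(seed=11, n_trials_patient=30, n_trials_healthy=60)
    space, stories, trials = simulate_study(cfg)
    return cfg, space, stories, trials
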