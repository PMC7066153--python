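"""Synthetic study generator: embeddings, stories, recall channel,
raters, transcript corruption, and whole-study structure."""

from __future__ import annotations

import math

import numpy as np
import pytest

from recallscore.features import extract_features
from recallscore.model import fit_ols, predict
from recallscore.reliability import word_error_rate
from recallscore.synthetic import (
    MINIMAL_RESPONSE,
    WER_PRESETS,
    SimulationConfig,
    corrupt_transcript,
    make_embeddings,
    make_recall,
    make_story,
    simulate_raters,
    simulate_study,
    substream,
    synonym_map,
)
from recallscore.textprep import TokenSequence


CFG = SimulationConfig(seed=3)


class TestMakeEmbeddings:
    def test_deterministic(self):
        s1, s2 = make_embeddings(CFG), make_embeddings(CFG)
        assert s1.vocab == s2.vocab
        for word in s1.vocab:
            np.testing.assert_array_equal(s1[word], s2[word])

    def test_synonym_pairs_are_mutual_nearest(self):
        space = make_embeddings(CFG)
        synonyms = synonym_map(CFG)
        words = sorted(space.vocab)
        mat = space.matrix(words)
        for a, b in list(synonyms.items())[:10]:
            da = np.linalg.norm(mat - space[a], axis=1)
            da[words.index(a)] = np.inf
            assert words[int(np.argmin(da))] == b
            assert np.linalg.norm(space[a] - space[b]) < CFG.synonym_epsilon

    def test_no_synonyms_keeps_words_separated(self):
        cfg = SimulationConfig(seed=4, n_synonym_pairs=0, vocab_size=100)
        space = make_embeddings(cfg)
        words = sorted(space.vocab)
        mat = space.matrix(words)
        dists = np.linalg.norm(mat[:, None, :] - mat[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 0.2  # Gaussian vectors: no accidental near-pairs


class TestMakeStory:
    def test_length_in_configured_range(self):
        lo, hi = CFG.story_length_range
        for i in range(10):
            assert lo <= len(make_story(CFG, i)) <= hi

    def test_minimal_range(self):
        cfg = SimulationConfig(seed=1, story_length_range=(5, 5))
        assert len(make_story(cfg, 0)) == 5

    def test_deterministic_per_index(self):
        assert make_story(CFG, 2).tokens == make_story(CFG, 2).tokens
        assert make_story(CFG, 2).tokens != make_story(CFG, 3).tokens

    def test_content_words_distinct_and_one_per_synonym_pair(self):
        story = make_story(CFG, 0)
        synonyms = synonym_map(CFG)
        content = [t for t in story.tokens if t.startswith("word")]
        assert len(content) == len(set(content))
        for token in content:
            partner = synonyms.get(token)
            if partner is not None:
                assert partner not in story.tokens


class TestMakeRecall:
    def setup_method(self):
        self.space = make_embeddings(CFG)
        self.story = make_story(CFG, 0)
        self.synonyms = synonym_map(CFG)

    def test_identity_channel(self):
        rng = substream(0, "t")
        recall, quality = make_recall(
            self.story, 1.0, 0.0, 0.0, self.space, rng, self.synonyms
        )
        assert recall.tokens == self.story.tokens
        assert quality == 1.0

    def test_total_forgetting(self):
        rng = substream(0, "t")
        recall, quality = make_recall(
            self.story, 0.0, 0.0, 0.0, self.space, rng, self.synonyms
        )
        assert recall.tokens == ()
        assert quality == 0.0

    def test_retention_matches_binomial_expectation(self):
        long_story = TokenSequence(tuple(f"word{i % 300:04d}" for i in range(10000)))
        rng = substream(1, "t")
        _, quality = make_recall(
            long_story, 0.5, 0.0, 0.0, self.space, rng, self.synonyms
        )
        se = math.sqrt(0.25 / 10000)
        assert abs(quality - 0.5) < 3 * se

    def test_synonym_substitution_uses_partner(self):
        story = TokenSequence(("word0000",))  # paired with word0001
        rng = substream(2, "t")
        recall, _ = make_recall(story, 1.0, 1.0, 0.0, self.space, rng, self.synonyms)
        assert recall.tokens == ("word0001",)


class TestSimulateRaters:
    def test_noiseless_mid_quality(self):
        rng = substream(0, "r")
        assert simulate_raters(0.5, 4, 0.0, rng) == [3.0, 3.0, 3.0, 3.0]

    def test_noiseless_perfect_recall(self):
        rng = substream(0, "r")
        assert simulate_raters(1.0, 3, 0.0, rng) == [6.0, 6.0, 6.0]

    def test_ratings_clamped_to_scale(self):
        rng = substream(1, "r")
        ratings = simulate_raters(1.0, 200, 3.0, rng)
        assert all(0.0 <= r <= 6.0 for r in ratings)
        assert any(r < 6.0 for r in ratings)  # noise actually perturbs


class TestCorruptTranscript:
    vocab = [f"word{i:04d}" for i in range(50)]

    def test_zero_target_identity(self):
        tokens = TokenSequence(tuple(self.vocab[:20]))
        rng = substream(0, "c")
        assert corrupt_transcript(tokens, 0.0, rng, self.vocab).tokens == tokens.tokens

    @pytest.mark.parametrize("target", [0.072, 0.105, 0.2, 0.233])
    def test_realized_wer_near_target(self, target):
        tokens = TokenSequence(tuple(self.vocab[i % 50] for i in range(100)))
        for trial in range(5):
            rng = substream(trial, "c")
            corrupted = corrupt_transcript(tokens, target, rng, self.vocab)
            _, rate = word_error_rate(tokens, corrupted)
            assert abs(rate - target) <= 0.05

    def test_deterministic_given_stream(self):
        tokens = TokenSequence(tuple(self.vocab[:60]))
        c1 = corrupt_transcript(tokens, 0.2, substream(5, "c"), self.vocab)
        c2 = corrupt_transcript(tokens, 0.2, substream(5, "c"), self.vocab)
        assert c1.tokens == c2.tokens


class TestSimulateStudy:
    def test_structure_and_determinism(self, small_study):
        cfg, space, stories, trials = small_study
        assert len(trials) == cfg.n_trials_patient + cfg.n_trials_healthy
        assert len(stories) == cfg.n_stories
        assert all(len(t.ratings) == cfg.n_raters for t in trials)
        assert all(0.0 <= r <= 6.0 for t in trials for r in t.ratings)
        assert all(set(t.corrupted_recalls) == set(WER_PRESETS) for t in trials)
        _, _, again = simulate_study(cfg)
        assert [t.recall.tokens for t in again] == [t.recall.tokens for t in trials]
        assert [t.ratings for t in again] == [t.ratings for t in trials]

    def test_short_response_tail_differs_by_cohort(self):
        cfg = SimulationConfig(seed=6, n_trials_patient=300, n_trials_healthy=300)
        _, _, trials = simulate_study(cfg)

        def minimal_fraction(group):
            members = [t for t in trials if t.group == group]
            return sum(
                t.recall.tokens == MINIMAL_RESPONSE for t in members
            ) / len(members)

        assert minimal_fraction("patient") > minimal_fraction("healthy")
        assert abs(minimal_fraction("patient") - cfg.p_minimal_patient) < 0.08
        assert abs(minimal_fraction("healthy") - cfg.p_minimal_healthy) < 0.05

    def test_group_contrast_direction(self, small_study):
        """Cohorts with different quality distributions produce the expected
        feature directions: healthy recalls share more types and sit closer
        in embedding space."""
        from recallscore.groupstats import cohen_d_from_samples

        cfg, space, stories, trials = small_study
        features = {
            t.response_id: extract_features(t.story, t.recall, space) for t in trials
        }
        ct = {"patient": [], "healthy": []}
        dist = {"patient": [], "healthy": []}
        for t in trials:
            fv = features[t.response_id]
            ct[t.group].append(fv.common_types)
            if not fv.wmd_missing:
                dist[t.group].append(fv.wmd)
        assert cohen_d_from_samples(ct["patient"], ct["healthy"]) > 0
        assert cohen_d_from_samples(dist["patient"], dist["healthy"]) < 0

    def test_mean_prediction_monotone_in_quality(self, small_study):
        """Binned mean predicted score is nondecreasing in recall quality
        over the grid q = 0.0, 0.2, ..., 1.0."""
        cfg, space, stories, trials = small_study
        feats, gold = [], []
        for t in trials:
            feats.append(extract_features(t.story, t.recall, space))
            gold.append(float(np.mean(t.ratings)))
        model = fit_ols(feats, gold)
        synonyms = synonym_map(cfg)
        story = stories[sorted(stories)[0]]
        means = []
        for step, q in enumerate([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]):
            preds = []
            for rep in range(12):
                rng = substream(cfg.seed, "monotone", step, rep)
                recall, _ = make_recall(
                    story, q, cfg.synonym_substitution_rate, cfg.filler_rate,
                    space, rng, synonyms,
                )
                fv = extract_features(story, recall, space)
                p = predict(model, fv)
                if not math.isnan(p):
                    preds.append(p)
            if preds:  # q=0 bins can be entirely unscorable (empty recalls)
                means.append(np.mean(preds))
        assert len(means) >= 5
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
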