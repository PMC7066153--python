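# Methods

## Scoring model

A transcribed story recall is scored against its prompt with two
features and a linear model.

**Preprocessing.** Text is Unicode case-folded; punctuation is removed
(apostrophes between word characters survive, hyphens split words);
tokens matching a hesitation lexicon (default: uh, um, er, ah, eh, hm,
hmm, mhm, uh-huh, um-hum; configurable) are dropped.  Multi-part
markers such as "uh-huh" are matched against whole whitespace chunks
before splitting, so they are removed as units.  No stemming, stop-word
removal or spelling correction is applied by default; a stop-word
switch exists (`PipelineConfig.remove_stopwords`, using scikit-learn's
English list) because some optimal-transport text-similarity pipelines
filter function words, but it is off since the scoring method's stated
preprocessing is only lowercasing, punctuation and filled-pause
removal.

**Common word types** is the size of the intersection of the distinct
word-type sets of prompt and recall.

**Word Mover's Distance (WMD).** Each document becomes a normalized
bag-of-words over its in-vocabulary types; out-of-vocabulary tokens are
dropped before normalization and counted per response.  WMD is the
optimal objective of the transportation linear program with the two
nBOW weight vectors as marginals and pairwise embedding distances as
costs, solved exactly with HiGHS (`scipy.optimize.linprog`); one
redundant marginal constraint is dropped to keep the system full-rank,
and tiny negative objectives from floating-point are clamped to zero.
The cost is the Euclidean distance between raw vectors (the classic WMD
formulation); cosine cost is available behind a config switch.  A
response with zero in-vocabulary tokens is *unscorable*: its WMD is a
NaN missing-marker that propagates to a missing prediction; it is never
an exception in the scoring path.  The word centroid distance (distance
between nBOW-weighted mean vectors) is provided as the standard lower
bound and is used as a verification aid in the tests.

**Model.** Ordinary least squares of the gold-standard rating (mean of
the human raters' 0–6 scores) on (common_types, wmd), fitted with
scikit-learn on responses with complete features; rank of the augmented
design is checked explicitly and rank-deficient designs raise a
dedicated error.  Predictions are not clipped to [0, 6] by default — the
raw model's behaviour on short responses is itself informative — with a
clip flag available.  Evaluation uses k-fold cross-validation (default
k = 5, response-level shuffle with a fixed seed): every response is
predicted by a model fitted without it, the pooled Pearson correlation
of held-out predictions against gold is the headline metric, and R² is
reported as pooled_r² (the pooled convention).  Per-fold correlations
are reported as a range check; folds too small or degenerate for a
correlation yield NaN entries rather than errors.  Response-level
(rather than participant-grouped) folds are the default because the
method's evaluation protocol divides responses into subsets; grouped
folds can be built by the caller from the fold-assignment map if
within-person leakage is a concern.

## Reliability and word error rate

Rater agreement is summarized as (a) each rater versus the mean of the
*other* raters on jointly rated responses (leave-one-out gold, the
default; an include-self convention is available since published
analyses are ambiguous between the two) and (b) Pearson correlations
for all rater pairs on jointly rated responses (pairs with fewer than 3
shared responses are omitted and logged; no imputation).

Word error rate uses a unit-cost Levenshtein alignment computed by
dynamic programming on preprocessed token sequences, so human and
machine transcripts are compared on an equal footing.  Hesitation
removal before WER is configurable and off by default, because ASR
filled-pause output is a genuine error source.  Among tied optimal
alignments the backtrace prefers substitution over insertion over
deletion; only the S+D+I total is contractual.  Corpus WER pools edit
counts over pooled reference length rather than averaging per-file
rates.  An empty reference with a non-empty hypothesis has an undefined
rate (NaN) but well-defined counts (all insertions).

## Group statistics

Cohorts are compared with two-sided Welch t-tests (scipy), pooled-SD
Cohen's d (classic d, not Hedges' g; sign = second group minus first),
and Holm step-down correction (statsmodels) over the family of measures
in one report run.  The package carries the published per-trial group
summaries of the validation study (patient n = 354 trials, healthy
n = 681) as reference inputs; recomputing d from those printed means
and SDs reproduces the published effect sizes at one-decimal precision
for word count (0.8), human rating (1.1) and predicted score (1.3).
The remaining printed effect sizes and all t statistics are not exactly
recoverable from one-decimal summaries (the effective n per measure is
not printed), so they are not asserted.

## Synthetic study generator

The generator emulates the validation study's structure so the whole
pipeline can be exercised without any restricted data.

* **Embeddings**: isotropic Gaussian vectors (expected unit norm) over a
  400-word vocabulary with 40 planted synonym pairs at mutual distance
  0.15 — each pair far closer than any unrelated word (typical distance
  √2).  Dimension 50: random Gaussian spaces of this size already give
  well-separated vocabularies, and nothing in the pipeline depends on
  the 300 dimensions typical of published embedding sets.
* **Stories**: 10 prompts of 62–87 words (the published prompt-length
  span pooled over narrative and instructional passages), mixing
  repeated function words (rate 0.35) with distinct content words, at
  most one member per synonym pair.
* **Recall channel**: token retention with probability q (the latent
  quality), nearest-neighbor synonym substitution of retained tokens
  with probability s = 0.10, filler insertion at rate f = 0.03, order
  preserved.  A Bernoulli retention channel is the simplest mechanism
  producing the observed feature directions; it is a modeling choice,
  not an empirical claim about memory.  q is drawn per trial from
  clipped normals — patients N(0.55, 0.22), healthy N(0.77, 0.18),
  matching the published group rating means/SDs rescaled to [0, 1] —
  and a short-response mixture replaces the recall with a fixed minimal
  3-token response ("i don't remember", whose words are in the
  vocabulary so it stays scorable, with quality 0) at probability 0.197
  for patients and 0.054 for healthy participants, the published
  short-response proportions.
* **Raters**: each rating is round(6q + ε) clamped to [0, 6], ε
  zero-mean Gaussian.  The default noise SD of 1.0 comes from the
  packaged grid-search calibration (`calibrate_rater_noise`) targeting a
  mean pairwise inter-rater correlation of 0.73 over 1000 mixed-cohort
  trials.
* **Corruption**: an error budget of ⌈WER·n⌉ operations split into equal
  thirds of substitutions, deletions and insertions (error-type
  proportions of real recognizers are not published; equal shares is
  the neutral choice).  Realized corpus WER lands slightly above the
  target (the per-transcript ceiling rounds up) but well within ±0.05
  for realistic lengths.  Presets: 0.072 (human transcription), 0.105
  (customized ASR), 0.233 (generic ASR).
* **Determinism**: all randomness derives from one seed through named
  substreams (seed, CRC-32 of the stream name, indices), so any
  component can be regenerated independently and identically.

What the generator does *not* emulate: acoustic variation, real ASR
error structure (confusions are uniform over the vocabulary, not
phonetically plausible), immediate-versus-delayed memory decay (the
position label is bookkeeping only), topic structure within stories,
and rater idiosyncrasies such as scale anchoring.  Passing tests
therefore demonstrate that the pipeline recovers graded recall quality
under a plausible generative model, not that it attains any particular
accuracy on clinical speech.

## Problem sizes and numerical choices

The acceptance script simulates 300 trials (100 patient / 200 healthy,
preserving the study's 1:2 ratio), the scale at which the stochastic
end-to-end properties (cross-validated pooled R > 0.7, clean-versus-
corrupted prediction correlation > 0.9) are stable across seeds; the
unit-test study uses 90 trials.  Oracle equivalence for the transport
solve is checked on 1000 random instances of ≤5-word documents against
a network-simplex min-cost-flow oracle with integerized marginals and
costs (exact to 1e-8), and on a subset against brute-force enumeration
of integer transport tables (integral marginals guarantee an integral
optimal vertex).  nBOW weights must sum to 1 within 1e-9; transport
objectives are compared at 1e-6; OLS against the normal equations at
1e-8.  Correlations require ≥3 observations and non-constant inputs,
raising explicit errors otherwise.
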