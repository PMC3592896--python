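# Methods

## Model

The predictor operates on a closed universe of `n` drugs with a symmetric
binary known-interaction matrix M₁ (zero diagonal) and per-edge free-text
effect annotations. A drug's interaction profile fingerprint is the sparse
row of M₁ — the sorted set of its partner indices. Similarity between
fingerprints is the Tanimoto coefficient |A∩B| / |A∪B|, assembled into the
symmetric matrix M₂ with a forced zero diagonal (self-interaction is not a
meaningful concept here).

Prediction is max-product propagation: the directed score of (i → j) is the
maximum, over the known partners k of drug i, of TC(k, j); the final score of
the unordered pair {i, j} is the larger of the two directions. Only the
single best similarity route is kept — multiple supporting routes do not
accumulate — and the predicted pair inherits the effect text of the known
interaction (anchor, k) behind the winning route. Known pairs are retained in
the prediction set with an `is_known` flag; filtering them out (and applying
a score cutoff) is a separate, explicit step.

Assumptions worth keeping in mind:

- **Closed system.** Scores are relative to the input database; drugs absent
  from it can never be predicted, and densely annotated drugs are easier to
  score than sparsely annotated ones.
- **Single-evidence scoring.** Keeping only the maximal route makes scores
  interpretable as "the best supporting similarity" but ignores convergent
  evidence from several routes.
- **No higher-order effects.** The model scores pairs only; interactions that
  emerge from triples of co-administered drugs, dosing, or bioavailability are
  out of scope.
- **Effect inheritance is a heuristic.** The inherited text is that of the
  anchor's known interaction; its reliability drops with the TC score of the
  prediction.

## Numerical conventions

- **Empty fingerprints.** TC(∅, ·) := 0, including TC(∅, ∅). An isolated drug
  carries no similarity evidence; this also keeps the zero diagonal consistent.
- **Mutual edge, unmasked by default.** When i and j themselves interact,
  position j sits in fp(i) and position i in fp(j). These positions are kept
  when comparing the two fingerprints (the worked example's arithmetic is
  consistent with unmasked sets); `mask_mutual=True` removes both from the
  union for users who prefer the leave-pair-out reading.
- **Ties.** When several neighbors k attain the maximal TC, the one with the
  lexicographically smallest identifier wins; when both directions of a pair
  tie, provenance comes from the direction whose anchor identifier is smaller.
  Drug indices are lexicographic by identifier, so both rules reduce to
  smallest-index argmax and the whole pipeline is byte-deterministic.
- **Omitted means zero.** Zero-score pairs and the diagonal are not stored;
  evaluation code treats absent pairs as score 0.
- **Precision of output.** Scores are held at full float64 precision;
  formatted output rounds to a configurable number of decimals (default 2 in
  the CLI, matching how such scores are conventionally printed).
- **Dense up to 5,000 drugs.** M₂ is assembled from one boolean matrix
  product (|A∩B| = A·Aᵀ); above 5,000 drugs the same computation runs in row
  blocks with bit-identical results.

## Evaluation

- **Hold-out.** `holdout_split` removes round(fraction × edges) edges
  uniformly at random (Python's round-half-to-even; drugs are never removed),
  rebuilds M₂/M₃ from the training edges only, and ranks the held-out pairs
  (positives) against every pair that is an edge of neither set (negatives —
  the maximal, assumption-free negative set). The ROC is a descending-score
  threshold sweep; with one threshold per unique score the trapezoidal area
  equals the Mann–Whitney statistic with half credit for ties, and the test
  suite checks this identity to 1e-12 against a brute-force pairwise oracle
  (and cross-checks scikit-learn's `roc_auc_score`).
- **Confusion statistics.** precision = TP/(TP+FP); random precision =
  universe_positives / universe_pairs, with the candidate universe supplied
  externally via `candidate_universe(n_drugs, focal_drugs)` =
  f·(n−1) − C(f, 2), the number of unordered non-self pairs touching at least
  one focal drug; enrichment factor = precision / random precision. The
  one-sided Fisher exact test (enrichment direction) is the upper
  hypergeometric tail P[X ≥ TP] via `scipy.stats.hypergeom.sf`, verified in
  tests against an exact rational tail sum for universes ≤ 2,000. No
  continuity correction.
- **Closed-form baselines.** `expected_random_hits` is the hypergeometric
  mean draws·K/N; `expected_overlap` is the expected intersection of two
  uniform random subsets, |S₁|·|S₂|/N.

## Synthetic data generator

Real interaction databases are organised by pharmacological class:
same-class drugs (e.g. anticholinergics) interact with largely the same
partners, which is the signal profile similarity exploits. The generator
states that world directly. Each of `n_classes` classes draws an archetype
set of `class_profile_size` partners from a pool of `n_target_drugs` target
drugs; each of `drugs_per_class` members inherits each archetype partner
independently with probability `share_prob` and gains, with probability
`noise_prob`, one uniformly random spurious target partner. Effects are a
deterministic function of the (class, target) pair, so class members inherit
identical annotations for the same target. All sampling flows through one
seeded generator; identical configs give identical networks.

Defaults: 20 classes × 10 drugs, 200 targets, 8-partner archetypes (the
worked example's fingerprint size), share_prob 0.9, noise_prob 0.02 — about
400 drugs and 1,450 edges, sparse with strong community structure, sized so
the full test battery runs in seconds. Target drugs are kept distinct from
class members so ground-truth classes stay cleanly recoverable.

What a green synthetic test does and does not establish: it shows the
pipeline recovers planted profile structure (held-out AUROC ≈ 0.99 at both
15% and 30% removal on the defaults) and that all estimators agree with
independent oracles. It does not certify real-world precision: real
interaction databases have heavy-tailed degree distributions, incomplete and
biased annotation, and correlated noise that the generator deliberately does
not model, and external reference standards disagree with any single source.
Published large-scale figures therefore cannot be reproduced from synthetic
data and are not claimed by the test suite.

## Known limitations

- Prediction quality is bounded by the coverage of the input database
  (absent drugs are invisible; sparse profiles score weakly).
- The candidate universe for enrichment statistics must be supplied by the
  caller; the package computes it only from (n_drugs, focal_drugs) counts.
- Effect text is opaque: no vocabulary normalisation or deduplication beyond
  first-occurrence-wins for conflicting duplicates (logged as a warning).
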