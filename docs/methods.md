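# Methods

## Model

A post *T* containing one drug mention *D* and one event mention *R* is
classified as causal (+1: the post asserts *R* was caused by *D*) or
non-causal (−1) by a linear rule over lexical patterns:

    h(T, D, R; w) = sgn(wᵀ f(T, D, R)),    sgn(x) = 1 if x > 0, −1 otherwise.

The convention sgn(0) = −1 is deliberate: a zero score means no pattern
evidence either way, and the safe default in signal detection is "not an
ADR report". There is no intercept by default (configurable), so the
all-zero feature vector — a post sharing no pattern with the training
vocabulary — is always classified negative.

### Features

The normalized token stream is split around the two entity spans into
prefix, midfix and postfix; the entity tokens themselves are excluded
everywhere, so features never encode particular drug or reaction names and
transfer to unseen ones. From each context we extract all n-grams for
n = 1, 2, 3 plus, for n ≥ 2, every variant with exactly one position
replaced by a wildcard matching any single token. The wildcard budget is
one per pattern; the bare wildcard unigram is excluded as uninformative.
"Skipping" is thus positional substitution inside a contiguous window, not
gapped subsequence extraction — every wildcard pattern has a fixed length
and matches fixed-length windows.

Features are boolean presence indicators (not counts) over the vocabulary
of all patterns extracted from the *training* posts, ordered
lexicographically on their serialized `TAG+tok+tok` form so dimensionality
and indices are reproducible. Test-time patterns outside the vocabulary are
dropped; the dimension never grows after fitting. An optional
document-frequency floor (`min_frequency`, default 1 = keep everything) can
prune hapax patterns.

### Tokenization

The tokenizer is deliberately minimal and fully specified, because the
pattern features are defined over its output: lowercase, split on
whitespace, then detach leading/trailing punctuation characters into
single-character tokens while keeping apostrophes (ASCII `'` and `’`)
word-internal. So `news:` → `news`, `:` but `i'm` stays whole. Interior
punctuation (hyphens, embedded colons) is kept. Each token records its
source character interval; entity spans must coincide with token boundaries
or segmentation fails loudly, naming the offending span.

### Learning

Weights come from the standard soft-margin primal

    min_w  ½‖w‖² + C Σ_n ξ_n   s.t.  y_n (w·x_n) ≥ 1 − ξ_n,  ξ_n ≥ 0.

Slack variables absorb annotation noise and make the boolean feature space
effectively separable; the cost C is the only hyperparameter and is tuned
on a held-out development split over the default grid {0.01, 0.1, 1, 10}
(ties resolved toward the smaller, i.e. more regularized, value). Only the
linear kernel is supported: interpretability of the per-pattern weights is
the point of the method, and top-k ranked positive/negative patterns plus
the count of weights at exactly zero (within tolerance 1e−12 — "exactly
zero" is ill-posed in floating point, so the tolerance is always reported
alongside the count) are first-class outputs.

The solver is liblinear (scikit-learn `LinearSVC`, hinge loss, dual
coordinate descent), which optimizes exactly this objective; the package
treats the primal objective value as the contract and the test suite checks
it against an independently solved box-constrained dual quadratic program
on small instances, and against closed-form KKT solutions of two toy
problems. Solver tolerance defaults to 1e−6; tests requiring optimality to
1e−4 use 1e−12.

## Evaluation protocol

Accuracy (100 × correct/total) is the only headline metric. Methods:
majority baseline (constant prediction of the more frequent training label,
ties toward −1), bag-of-words (boolean unigram presence over non-entity
tokens, same SVM machinery), the three single-segment and three
paired-segment ablations, and the full three-segment model.

Cross-validation is stratified k-fold (default k = 5) from a seeded
shuffle; the pattern vocabulary is refit inside each fold on the training
portion only, so no test-fold pattern ever reaches the model. Pooled
(micro) accuracy over held-out folds is the headline number — the
aggregation is not forced by the protocol, so per-fold accuracies are kept
in the report. Uncertainty is an exact Clopper–Pearson binomial interval on
the pooled correct count: lower = Beta(k, n−k+1) quantile at α/2 (0 when
k = 0), upper = Beta(k+1, n−k) quantile at 1−α/2 (1 when k = n). A method
is called significantly better than the majority baseline when its pooled
accuracy exceeds the baseline's interval upper bound at the chosen
confidence (default 99.9%).

## Synthetic corpus

The generator produces the statistical structure the method assumes, not
realistic language. Per post: label from the class balance (default 47.2%
positive — most drug–event co-mentions in a realistic stream are not
causal), entity order uniform, and per segment 0–3 filler tokens from a
small class-independent vocabulary plus, with the segment's injection
probability, one cue phrase from the label's lexicon. Default injection
probabilities are {prefix 0.4, midfix 0.7, postfix 0.4}: the midfix is made
the most informative context, so segment-ablation experiments have a known
qualitative ordering to recover. Positive cues are intake markers and
causal verbs ("took", "high off", "induced", "now feeling", …); negative
cues are advertising/hedging/negation markers ("commercial", "don't
think", "not because", …). Posts are capped at 140 characters; fillers
(never cues) are shed to fit.

Because the positive and negative cue lexicons share no tokens (and fillers
overlap neither), the Bayes-optimal accuracy is closed-form: with
per-segment injection probabilities p_seg and positive fraction q,

    P(no cue) = Π_seg (1 − p_seg)
    Bayes accuracy = 1 − P(no cue) + P(no cue) · max(q, 1 − q),

94.9% at the defaults. This gives tests a hard ceiling (trained accuracy
must approach but not significantly exceed it) and a planted structure
(each cue phrase's exact tagged n-gram must receive a weight of the cue's
class sign).

What the generator does **not** emulate: real lexical diversity and Zipfian
vocabularies, misspellings, sarcasm, negation scope, multi-drug posts, or
annotation noise. Passing tests therefore demonstrate correctness of the
pipeline and recoverability of planted structure — not field performance on
real social-media text, whose accuracies with this method are substantially
lower than the synthetic ceiling.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical claims are comfortably resolved: 5,000 posts
for harness and structure-recovery checks, 1,500 × 10 seeds for the
ablation ordering, 600 × 10 seeds for the no-signal control, a 500+500
development split for cost tuning. Randomness flows from explicit seeds
everywhere (corpus generation, fold shuffling, development carving);
identical seeds give identical corpora, folds and accuracies.

Degenerate inputs fail loudly: empty text, spans off token boundaries,
overlapping spans, single-class training sets, non-positive C, empty tuning
grids, classes smaller than k for folding. Model files are plain text with
`repr`-round-tripped float weights and a vocabulary hash, so a save/load
cycle reproduces decision values bit-for-bit (decision values are computed
with a fixed summation order over sorted active indices).

## Known limitations

- The tokenizer is an explicit design choice; real tweet tokenization
  (hashtags, @-handles, emoji) is reduced to generic punctuation handling.
- Drug/event mention detection is assumed given; the package classifies
  annotated co-mentions only.
- Accuracy is the only built-in metric (by protocol); precision/recall can
  be computed from the prediction output but are not part of the report.
- The bag-of-words baseline is unrealistically strong on the synthetic
  corpus, where single cue unigrams identify the class; on real text,
  word-order-sensitive patterns carry more of the signal.
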