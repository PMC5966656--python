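"""Train the pattern-weight SVM on a synthetic corpus and inspect the weights.

The linear kernel keeps the model interpretable: each weight is the influence
of one skip-gram pattern on the causality decision, so the top positively and
negatively weighted patterns read as a learned cue lexicon.
"""

from adrcause import (
    MethodConfig,
    SyntheticConfig,
    evaluate_holdout,
    generate_corpus,
    stratified_holdout_split,
    top_k_patterns,
    zero_weight_stats,
)

posts = generate_corpus(SyntheticConfig(n_posts=2000, seed=42))
train, test = stratified_holdout_split(posts, test_fraction=0.2, seed=42)

result = evaluate_holdout(train, test, MethodConfig(features="pms", C=1.0))
model = result.model
print(f"trained on {len(train)} posts, {model.d} pattern features")
print(f"held-out accuracy: {result.accuracy:.2f}% ({result.n_correct}/{result.n_test})")

stats = zero_weight_stats(model)
print(f"weights exactly zero: {stats.count} ({100 * stats.fraction:.1f}% pruned as uninformative)")

print("\ntop positive patterns (evidence FOR causality):")
for label, w in top_k_patterns(model, 5, "+"):
    print(f"  {label:<24}{w: .4f}")
print("top negative patterns (evidence AGAINST):")
for label, w in top_k_patterns(model, 5, "-"):
    print(f"  {label:<24}{w: .4f}")

# The planted generator cues (e.g. M+induced, P+took for positives;
# M+commercial, P+don't+think for negatives) should dominate both lists.
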