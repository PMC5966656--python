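"""The synthetic generator's knobs and its closed-form Bayes optimum.

Cue phrases are injected per segment with configurable probabilities; since
positive and negative cue lexicons share no tokens, the Bayes-optimal
accuracy is exact: a post is classifiable iff any cue landed, otherwise the
best guess is the majority class. The trained model should approach — never
exceed, up to sampling noise — this ceiling.
"""

from adrcause import (
    MethodConfig,
    SyntheticConfig,
    evaluate_holdout,
    generate_corpus,
    oracle_accuracy,
    stratified_holdout_split,
)

for prob in (0.0, 0.3, 0.6, 0.9):
    config = SyntheticConfig(n_posts=2000, cue_injection_prob=prob, seed=1)
    posts = generate_corpus(config)
    train, test = stratified_holdout_split(posts, test_fraction=0.25, seed=1)
    res = evaluate_holdout(train, test, MethodConfig(features="pms"))
    maj = evaluate_holdout(train, test, MethodConfig(features="majority"))
    print(
        f"cue prob {prob:.1f}: Bayes optimum {oracle_accuracy(config):6.2f}%  "
        f"model {res.accuracy:6.2f}%  majority {maj.accuracy:6.2f}%"
    )

# At prob 0 the model has nothing to learn and sits at the majority level;
# as injection rises, accuracy climbs toward the closed-form ceiling.
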