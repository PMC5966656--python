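"""Accuracy, baselines, Clopper–Pearson intervals and the CV harness."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from adrcause import (
    InvalidInputError,
    MethodConfig,
    SyntheticConfig,
    accuracy,
    clopper_pearson_ci,
    cross_validate,
    generate_corpus,
    majority_baseline,
    make_folds,
)

from oracles import counting_accuracy


def test_accuracy_examples_and_counting_oracle():
    assert accuracy([1, 1, -1, -1], [1, 1, -1, 1]) == 75.0
    assert accuracy([1, -1], [1, -1]) == 100.0
    rng = np.random.default_rng(5)
    preds = np.where(rng.random(1000) < 0.5, 1, -1)
    labels = np.where(rng.random(1000) < 0.5, 1, -1)
    assert accuracy(preds, labels) == counting_accuracy(preds, labels)


def test_accuracy_rejects_mismatch_and_empty():
    with pytest.raises(InvalidInputError):
        accuracy([1], [1, -1])
    with pytest.raises(InvalidInputError):
        accuracy([], [])


def test_majority_baseline_definition_and_tie_rule():
    train = [-1] * 6 + [1] * 4
    test = [-1] * 6 + [1] * 4
    assert majority_baseline(train, test) == 60.0
    # balanced training labels: tie broken toward the negative class
    tied = [-1, 1, -1, 1]
    assert majority_baseline(tied, [-1, -1, 1, 1]) == 50.0
    assert majority_baseline(tied, [-1, -1, -1, 1]) == 75.0


def test_clopper_pearson_boundaries_exact():
    assert clopper_pearson_ci(0, 10, 0.95)[0] == 0.0
    assert clopper_pearson_ci(10, 10, 0.95)[1] == 1.0


def test_clopper_pearson_known_value():
    lo, hi = clopper_pearson_ci(8, 10, 0.95)
    assert lo == pytest.approx(0.44390, abs=1e-4)
    assert hi == pytest.approx(0.97479, abs=1e-4)


def test_clopper_pearson_matches_statsmodels_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(1, 500))
        k = int(rng.integers(0, n + 1))
        conf = float(rng.uniform(0.5, 0.999))
        lo, hi = clopper_pearson_ci(k, n, conf)
        elo, ehi = proportion_confint(k, n, alpha=1 - conf, method="beta")
        assert lo == pytest.approx(0.0 if k == 0 else elo, abs=1e-10)
        assert hi == pytest.approx(1.0 if k == n else ehi, abs=1e-10)


def test_clopper_pearson_interval_width_behavior():
    lo1, hi1 = clopper_pearson_ci(60, 100, 0.95)
    lo2, hi2 = clopper_pearson_ci(600, 1000, 0.95)
    assert (hi2 - lo2) < (hi1 - lo1)  # shrinks with trials at fixed proportion
    lo3, hi3 = clopper_pearson_ci(60, 100, 0.999)
    assert (hi3 - lo3) > (hi1 - lo1)  # widens with confidence


def test_clopper_pearson_rejects_bad_parameters():
    with pytest.raises(InvalidInputError):
        clopper_pearson_ci(5, 4, 0.95)
    with pytest.raises(InvalidInputError):
        clopper_pearson_ci(1, 4, 1.5)


def test_folds_partition_stratify_and_determinism():
    labels = [1] * 47 + [-1] * 53
    split = make_folds(labels, k=5, seed=3)
    all_test = [i for _, te in split.folds for i in te]
    assert sorted(all_test) == list(range(100))  # disjoint + exhaustive
    global_pos = 0.47
    for tr, te in split.folds:
        assert set(tr) | set(te) == set(range(100))
        assert set(tr) & set(te) == set()
        n_pos = sum(1 for i in te if labels[i] == 1)
        assert abs(n_pos - global_pos * len(te)) <= 1.0
    assert make_folds(labels, k=5, seed=3) == split
    assert make_folds(labels, k=5, seed=4) != split


def test_folds_reject_class_smaller_than_k():
    with pytest.raises(InvalidInputError):
        make_folds([1] * 3 + [-1] * 50, k=5)


@pytest.fixture(scope="module")
def cv_corpus():
    return generate_corpus(SyntheticConfig(n_posts=300, seed=21))


def test_cv_pooled_count_conservation_and_determinism(cv_corpus):
    cfg = MethodConfig(features="pms", n_max=2)
    r1 = cross_validate(cv_corpus, cfg, k=5, seed=9)
    r2 = cross_validate(cv_corpus, cfg, k=5, seed=9)
    assert r1.n_correct == sum(f.n_correct for f in r1.folds)
    assert r1.n_total == len(cv_corpus)
    assert [f.accuracy for f in r1.folds] == [f.accuracy for f in r2.folds]
    lo, hi = r1.ci
    assert lo <= r1.pooled_accuracy <= hi
    assert 0 <= lo <= hi <= 100


def test_cv_majority_matches_direct_definition(cv_corpus):
    r = cross_validate(cv_corpus, MethodConfig(features="majority"), k=5, seed=9)
    labels = [p.label for p in cv_corpus]
    # class balance is preserved by stratification, so every fold predicts -1
    expected = 100.0 * labels.count(-1) / len(labels)
    assert r.pooled_accuracy == pytest.approx(expected, abs=1e-9)


def test_cv_vocabulary_never_leaks_test_patterns(cv_corpus):
    """Fold vocabularies come from training posts only."""
    from adrcause.evaluation import _pattern_cache, _vocab_from_sets

    posts = cv_corpus[:100]
    labels = [p.label for p in posts]
    split = make_folds(labels, k=5, seed=0)
    cache = _pattern_cache(posts, 2, 1)
    for tr, te in split.folds:
        vocab = _vocab_from_sets([cache[i] for i in tr], ("P", "M", "S"), 1, 2, 1)
        train_union = set().union(*(cache[i] for i in tr))
        assert set(vocab.patterns) <= train_union


def test_cv_with_grid_tunes_C(cv_corpus):
    cfg = MethodConfig(features="pms", n_max=2, C_grid=(0.1, 1.0))
    r = cross_validate(cv_corpus, cfg, k=3, seed=1)
    assert all(f.chosen_C in (0.1, 1.0) for f in r.folds)
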