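"""Linear SVM training, prediction semantics, weight inspection, persistence."""

import numpy as np
import pytest

from adrcause import (
    FeatureVector,
    InvalidInputError,
    TrainedModel,
    TrainingError,
    decision_value,
    fit_vocabulary,
    load_model,
    predict,
    predict_matrix,
    save_model,
    to_csr,
    top_k_patterns,
    train_svm,
    tune_C,
    vectorize,
    zero_weight_stats,
)
from adrcause.classifier import primal_objective
from adrcause.evaluation import _feature_config_dict, MethodConfig

from oracles import svm_dual_qp

RNG = np.random.default_rng(42)


def test_closed_form_1d_toy():
    """min ½w² s.t. w ≥ 1 has solution w = 1."""
    m = train_svm(np.array([[1.0], [-1.0]]), [1, -1], C=1e4, tolerance=1e-12)
    assert abs(m.weights[0] - 1.0) < 1e-6


def test_closed_form_2d_toy():
    """Symmetric separable pair: w = (0.5, 0.5)."""
    m = train_svm(np.array([[1.0, 1.0], [-1.0, -1.0]]), [1, -1], C=1e4, tolerance=1e-12)
    assert np.allclose(m.weights, [0.5, 0.5], atol=1e-6)


def test_separable_data_reaches_perfect_training_accuracy():
    X = np.vstack([RNG.normal(2, 0.3, (20, 3)), RNG.normal(-2, 0.3, (20, 3))])
    y = [1] * 20 + [-1] * 20
    m = train_svm(X, y, C=1e3, tolerance=1e-10)
    assert np.all(predict_matrix(m, X) == np.array(y))


@pytest.mark.parametrize("trial", range(8))
def test_primal_objective_matches_dual_qp_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    X = (rng.random((10, 5)) < 0.4).astype(float)
    y = np.where(rng.random(10) < 0.5, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[1]
    C = [0.1, 1.0, 10.0][trial % 3]
    m = train_svm(X, y, C=C, tolerance=1e-12)
    _, oracle_obj = svm_dual_qp(X, y, C)
    assert abs(primal_objective(m, X, y) - oracle_obj) < 1e-4


def test_objective_never_worse_than_zero_weights():
    X = (RNG.random((30, 8)) < 0.3).astype(float)
    y = np.where(RNG.random(30) < 0.5, 1, -1)
    y[:2] = [1, -1]
    C = 1.0
    m = train_svm(X, y, C=C, tolerance=1e-10)
    assert primal_objective(m, X, y) <= C * len(y) + 1e-9


def test_degenerate_inputs_rejected():
    with pytest.raises(TrainingError):
        train_svm(np.ones((3, 2)), [1, 1, 1], C=1.0)
    with pytest.raises(InvalidInputError):
        train_svm(np.eye(2), [1, -1], C=0.0)
    with pytest.raises(InvalidInputError):
        train_svm(np.eye(2), [1], C=1.0)


def test_sign_convention_zero_is_negative():
    m = TrainedModel(weights=np.array([0.5, -0.5]), C=1.0)
    assert predict(m, np.array([1.0, 1.0])) == -1  # decision exactly 0
    assert predict(m, np.array([2.0, 1.0])) == 1  # decision 0.5
    assert predict(m, FeatureVector(2, ())) == -1  # all-zero input
    assert decision_value(m, FeatureVector(2, (0,))) == 0.5


def test_dimension_mismatch_rejected():
    m = TrainedModel(weights=np.zeros(3), C=1.0)
    with pytest.raises(InvalidInputError):
        decision_value(m, FeatureVector(2, (0,)))
    with pytest.raises(InvalidInputError):
        predict_matrix(m, np.zeros((2, 4)))


def test_tune_C_single_element_grid_and_tie_break():
    X = np.vstack([np.ones((10, 1)), -np.ones((10, 1))])
    y = [1] * 10 + [-1] * 10
    assert tune_C((X, y), (X, y), grid=[0.5]) == 0.5
    # all grid values reach the same dev accuracy -> smallest C wins
    assert tune_C((X, y), (X, y), grid=[10.0, 0.01, 1.0]) == 0.01


def test_tune_C_rejects_empty_or_nonpositive_grid():
    X = np.eye(2)
    y = [1, -1]
    with pytest.raises(InvalidInputError):
        tune_C((X, y), (X, y), grid=[])
    with pytest.raises(InvalidInputError):
        tune_C((X, y), (X, y), grid=[-1.0])


def test_top_k_patterns_ordering(small_corpus):
    vocab = fit_vocabulary(small_corpus[:5])
    w = RNG.normal(0, 1, len(vocab))
    m = TrainedModel(weights=w, C=1.0, vocabulary=vocab)
    top_pos = top_k_patterns(m, 3, "+")
    assert [x[1] for x in top_pos] == sorted(w, reverse=True)[:3]
    top_neg = top_k_patterns(m, 3, "-")
    assert [x[1] for x in top_neg] == sorted(w)[:3]
    # k > d returns everything; + and - together cover all weights
    assert len(top_k_patterns(m, len(vocab) + 10, "+")) == len(vocab)
    allw = {x[0] for x in top_k_patterns(m, len(vocab), "+")}
    assert allw == set(vocab.labels)


def test_zero_weight_stats_counts_and_histogram():
    m = TrainedModel(weights=np.array([0.0, 0.0, 1.0]), C=1.0)
    s = zero_weight_stats(m)
    assert s.count == 2
    assert s.fraction == pytest.approx(2 / 3)
    assert sum(s.hist_counts) == 3
    assert 0.0 <= s.fraction <= 1.0


def test_model_save_load_reproduces_predictions_bitwise(tmp_path, small_corpus):
    train_posts = small_corpus[:60]
    vocab = fit_vocabulary(train_posts)
    fvs = [vectorize(p, vocab) for p in train_posts]
    y = [p.label for p in train_posts]
    m = train_svm(
        to_csr(fvs), y, C=1.0, vocabulary=vocab,
        feature_config=_feature_config_dict(MethodConfig(features="pms")),
    )
    path = tmp_path / "model.tsv"
    save_model(m, path)
    m2 = load_model(path)
    assert np.array_equal(m.weights, m2.weights)  # exact, not approximate
    assert m2.vocabulary.labels == vocab.labels
    for fv in fvs:
        assert decision_value(m, fv) == decision_value(m2, fv)
        assert predict(m, fv) == predict(m2, fv)
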