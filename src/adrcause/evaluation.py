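"""Evaluation protocol: accuracy, baselines, stratified CV, exact binomial CIs.

The protocol mirrors a standard text-classification study design:

* accuracy = 100 × correct / total (the only headline metric);
* a majority-class baseline (constant prediction of the more frequent
  training label, ties resolved toward the negative class);
* a bag-of-words linear-SVM baseline (order-free unigram presence);
* segment ablations — patterns from any subset of {prefix, midfix, postfix};
* stratified k-fold cross-validation from a seeded shuffle, with the pattern
  vocabulary refit inside each fold on the training portion only (no leakage);
* exact Clopper–Pearson binomial confidence intervals on pooled accuracy,
  used to test methods against the majority baseline without multiple
  pairwise comparisons.

Pooled (micro) accuracy over all held-out folds is the headline number;
per-fold accuracies are retained in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.stats import beta as beta_dist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import TrainedModel, predict_matrix, train_svm, tune_C
from .exceptions import InvalidInputError
from .features import PatternVocabulary, TokenVocabulary, bow_token_set
from .patterns import SEGMENT_TAGS, SkipGramPattern, extract_post_patterns
from .segmentation import AnnotatedPost, segment_post

__all__ = [
    "accuracy",
    "majority_baseline",
    "clopper_pearson_ci",
    "FoldSplit",
    "make_folds",
    "MethodConfig",
    "FEATURE_SETS",
    "FoldResult",
    "EvaluationReport",
    "cross_validate",
    "HoldoutResult",
    "evaluate_holdout",
    "stratified_holdout_split",
    "carve_dev_set",
]

# Feature-set selectors: segment subsets, the order-free unigram baseline and
# the constant majority predictor.
FEATURE_SETS: Dict[str, Optional[Tuple[str, ...]]] = {
    "p": ("P",),
    "m": ("M",),
    "s": ("S",),
    "pm": ("P", "M"),
    "ps": ("P", "S"),
    "ms": ("M", "S"),
    "pms": ("P", "M", "S"),
    "bow": None,
    "majority": None,
}


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Percentage of correct predictions."""
    preds = np.asarray(list(predictions))
    labs = np.asarray(list(labels))
    if preds.shape != labs.shape or preds.size == 0:
        raise InvalidInputError("predictions and labels must be equal-length and non-empty")
    return 100.0 * float(np.mean(preds == labs))


def majority_baseline(train_labels: Sequence[int], test_labels: Sequence[int]) -> float:
    """Accuracy of constantly predicting the training majority (ties → −1)."""
    tr = list(train_labels)
    if not tr:
        raise InvalidInputError("training labels are empty")
    maj = 1 if tr.count(1) > tr.count(-1) else -1
    return accuracy([maj] * len(list(test_labels)), test_labels)


def clopper_pearson_ci(successes: int, trials: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if trials < 1 or not (0 <= successes <= trials):
        raise InvalidInputError(f"need 0 <= successes <= trials >= 1, got {successes}/{trials}")
    if not (0.0 < confidence < 1.0):
        raise InvalidInputError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


@dataclass(frozen=True)
class FoldSplit:
    """Stratified partition of a dataset into k disjoint, exhaustive folds."""

    k: int
    seed: int
    assignments: Tuple[int, ...]
    folds: Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], ...]  # (train_idx, test_idx) per fold


def make_folds(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k folds from a seeded shuffle.

    Raises
    ------
    InvalidInputError
        If either class has fewer than ``k`` members.
    """
    labs = np.asarray(list(labels))
    for cls in (-1, 1):
        if int(np.sum(labs == cls)) < k:
            raise InvalidInputError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(labs.shape[0], -1, dtype=int)
    folds = []
    for f, (tr, te) in enumerate(skf.split(np.zeros((labs.shape[0], 1)), labs)):
        assignments[te] = f
        folds.append((tuple(int(i) for i in tr), tuple(int(i) for i in te)))
    return FoldSplit(k=k, seed=seed, assignments=tuple(int(a) for a in assignments), folds=tuple(folds))


@dataclass(frozen=True)
class MethodConfig:
    """One row of the study design: feature set plus extraction/SVM settings.

    ``C_grid`` set (and ``C`` ignored) means the cost is tuned on a development
    split carved out of the training portion.
    """

    features: str = "pms"
    n_max: int = 3
    max_wildcards: int = 1
    min_frequency: int = 1
    C: float = 1.0
    C_grid: Optional[Tuple[float, ...]] = None
    dev_fraction: float = 0.1
    fit_intercept: bool = False

    def __post_init__(self) -> None:
        if self.features not in FEATURE_SETS:
            raise InvalidInputError(
                f"features must be one of {sorted(FEATURE_SETS)}, got {self.features!r}"
            )


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n_test: int
    n_correct: int
    accuracy: float
    chosen_C: Optional[float] = None
    vocab_size: Optional[int] = None


@dataclass
class EvaluationReport:
    """Per-fold and pooled accuracies with an exact binomial interval (in %)."""

    method: str
    k: int
    seed: int
    confidence: float
    folds: List[FoldResult] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(f.n_test for f in self.folds)

    @property
    def n_correct(self) -> int:
        return sum(f.n_correct for f in self.folds)

    @property
    def pooled_accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def ci(self) -> Tuple[float, float]:
        lo, hi = clopper_pearson_ci(self.n_correct, self.n_total, self.confidence)
        return 100.0 * lo, 100.0 * hi


# ----------------------------------------------------------------- caching --
# Pattern extraction is the expensive step, and it does not depend on the
# fold, so the full-extraction set per post is computed once and reused:
# fold vocabularies are tag-filtered unions over training posts.


def _pattern_cache(
    posts: Sequence[AnnotatedPost], n_max: int, max_wildcards: int
) -> List[FrozenSet[SkipGramPattern]]:
    return [
        frozenset(extract_post_patterns(segment_post(p), n_max, max_wildcards))
        for p in posts
    ]


def _bow_cache(posts: Sequence[AnnotatedPost]) -> List[FrozenSet[str]]:
    return [frozenset(bow_token_set(p)) for p in posts]


def _vocab_from_sets(
    train_sets: Sequence[FrozenSet[SkipGramPattern]],
    segments: Tuple[str, ...],
    min_frequency: int,
    n_max: int,
    max_wildcards: int,
) -> PatternVocabulary:
    seg_set = set(segments)
    df: Dict[SkipGramPattern, int] = {}
    for s in train_sets:
        for p in s:
            if p.segment_tag in seg_set:
                df[p] = df.get(p, 0) + 1
    return PatternVocabulary(
        (p for p, c in df.items() if c >= min_frequency),
        n_max=n_max,
        max_wildcards=max_wildcards,
        segments=segments,
    )


def _matrix_from_sets(sets: Sequence[FrozenSet], index: Dict, d: int) -> csr_matrix:
    indptr = [0]
    indices: list[int] = []
    for s in sets:
        row = sorted(index[x] for x in s if x in index)
        indices.extend(row)
        indptr.append(len(indices))
    return csr_matrix(([1.0] * len(indices), indices, indptr), shape=(len(sets), d))


def _fit_fold(
    config: MethodConfig,
    train_sets,
    test_sets,
    y_train: np.ndarray,
    tolerance: float,
    dev_seed: int,
):
    """Fit one feature set on one training split; returns (model, vocab, X_test)."""
    if config.features == "bow":
        vocab: object = TokenVocabulary(t for s in train_sets for t in s)
        index = {t: i for i, t in enumerate(vocab.labels)}
    else:
        segments = FEATURE_SETS[config.features]
        vocab = _vocab_from_sets(
            train_sets, segments, config.min_frequency, config.n_max, config.max_wildcards
        )
        index = {p: i for i, p in enumerate(vocab.patterns)}
    d = len(vocab.labels)
    X_train = _matrix_from_sets(train_sets, index, d)
    X_test = _matrix_from_sets(test_sets, index, d)
    chosen_C = config.C
    if config.C_grid:
        sub_tr, sub_dev = train_test_split(
            np.arange(len(train_sets)),
            test_size=config.dev_fraction,
            stratify=y_train,
            random_state=dev_seed,
        )
        chosen_C = tune_C(
            (X_train[sub_tr], y_train[sub_tr]),
            (X_train[sub_dev], y_train[sub_dev]),
            grid=config.C_grid,
            tolerance=tolerance,
            fit_intercept=config.fit_intercept,
        )
    model = train_svm(
        X_train,
        y_train,
        C=chosen_C,
        tolerance=tolerance,
        fit_intercept=config.fit_intercept,
        vocabulary=vocab,
        feature_config=_feature_config_dict(config),
    )
    return model, X_test, chosen_C, d


def _feature_config_dict(config: MethodConfig) -> Dict:
    if config.features == "bow":
        return {"kind": "bow"}
    return {
        "kind": "pattern",
        "segments": list(FEATURE_SETS[config.features]),
        "n_max": config.n_max,
        "max_wildcards": config.max_wildcards,
        "min_frequency": config.min_frequency,
    }


def cross_validate(
    posts: Sequence[AnnotatedPost],
    config: Optional[MethodConfig] = None,
    k: int = 5,
    seed: int = 0,
    confidence: float = 0.999,
    tolerance: float = 1e-6,
    cache=None,
) -> EvaluationReport:
    """Run the stratified k-fold protocol for one method configuration.

    The vocabulary is refit on each fold's training portion; test-fold-only
    patterns never enter the model. ``cache`` (from a prior run over the same
    ``posts``) lets callers evaluate several feature sets without re-extracting.
    """
    config = config or MethodConfig()
    labels = _require_labels(posts)
    split = make_folds(labels, k=k, seed=seed)
    report = EvaluationReport(method=config.features, k=k, seed=seed, confidence=confidence)
    if config.features == "majority":
        for f, (tr, te) in enumerate(split.folds):
            maj = 1 if list(labels[list(tr)]).count(1) > list(labels[list(tr)]).count(-1) else -1
            n_correct = int(np.sum(labels[list(te)] == maj))
            report.folds.append(
                FoldResult(f, len(te), n_correct, 100.0 * n_correct / len(te))
            )
        return report
    if cache is None:
        cache = (
            _bow_cache(posts)
            if config.features == "bow"
            else _pattern_cache(posts, config.n_max, config.max_wildcards)
        )
    for f, (tr, te) in enumerate(split.folds):
        tr_l, te_l = list(tr), list(te)
        model, X_test, chosen_C, d = _fit_fold(
            config,
            [cache[i] for i in tr_l],
            [cache[i] for i in te_l],
            labels[tr_l],
            tolerance,
            dev_seed=(seed * 1009 + f) % (2**31 - 1),
        )
        preds = predict_matrix(model, X_test)
        n_correct = int(np.sum(preds == labels[te_l]))
        report.folds.append(
            FoldResult(f, len(te_l), n_correct, 100.0 * n_correct / len(te_l), chosen_C, d)
        )
    return report


@dataclass
class HoldoutResult:
    model: Optional[TrainedModel]
    accuracy: float
    n_correct: int
    n_test: int
    chosen_C: Optional[float] = None


def stratified_holdout_split(
    posts: Sequence[AnnotatedPost], test_fraction: float = 0.2, seed: int = 0
) -> Tuple[List[AnnotatedPost], List[AnnotatedPost]]:
    """Seeded stratified train/test split of labeled posts."""
    labels = _require_labels(posts)
    idx_tr, idx_te = train_test_split(
        np.arange(len(posts)), test_size=test_fraction, stratify=labels, random_state=seed
    )
    return [posts[i] for i in idx_tr], [posts[i] for i in idx_te]


def carve_dev_set(
    posts: Sequence[AnnotatedPost], n_per_class: int, seed: int = 0
) -> Tuple[List[AnnotatedPost], List[AnnotatedPost]]:
    """Set aside ``n_per_class`` posts of each label as a development set."""
    labels = _require_labels(posts)
    rng = np.random.default_rng(seed)
    dev_idx: Set[int] = set()
    for cls in (-1, 1):
        cls_idx = np.flatnonzero(labels == cls)
        if cls_idx.size < n_per_class + 1:
            raise InvalidInputError(
                f"class {cls} has {cls_idx.size} posts, cannot carve {n_per_class} for dev"
            )
        dev_idx.update(int(i) for i in rng.permutation(cls_idx)[:n_per_class])
    dev = [posts[i] for i in sorted(dev_idx)]
    rest = [p for i, p in enumerate(posts) if i not in dev_idx]
    return rest, dev


def evaluate_holdout(
    train_posts: Sequence[AnnotatedPost],
    test_posts: Sequence[AnnotatedPost],
    config: Optional[MethodConfig] = None,
    tolerance: float = 1e-6,
    seed: int = 0,
) -> HoldoutResult:
    """Train on one split, evaluate on another (no cross-validation)."""
    config = config or MethodConfig()
    y_train = _require_labels(train_posts)
    y_test = _require_labels(test_posts)
    if config.features == "majority":
        maj = 1 if list(y_train).count(1) > list(y_train).count(-1) else -1
        n_correct = int(np.sum(y_test == maj))
        return HoldoutResult(None, 100.0 * n_correct / len(y_test), n_correct, len(y_test))
    if config.features == "bow":
        train_sets = _bow_cache(train_posts)
        test_sets = _bow_cache(test_posts)
    else:
        train_sets = _pattern_cache(train_posts, config.n_max, config.max_wildcards)
        test_sets = _pattern_cache(test_posts, config.n_max, config.max_wildcards)
    model, X_test, chosen_C, _ = _fit_fold(
        config, train_sets, test_sets, y_train, tolerance, dev_seed=seed % (2**31 - 1)
    )
    preds = predict_matrix(model, X_test)
    n_correct = int(np.sum(preds == y_test))
    return HoldoutResult(
        model, 100.0 * n_correct / len(y_test), n_correct, len(y_test), chosen_C
    )


def _require_labels(posts: Sequence[AnnotatedPost]) -> np.ndarray:
    if len(posts) == 0:
        raise InvalidInputError("no posts given")
    labels = []
    for p in posts:
        if p.label is None:
            raise InvalidInputError(f"post {p.id!r} has no label")
        labels.append(p.label)
    return np.asarray(labels)
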