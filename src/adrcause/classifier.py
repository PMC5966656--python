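"""Soft-margin linear SVM over boolean pattern features.

The model is the classic L2-regularized hinge-loss primal

    min_w  ½‖w‖² + C · Σ_n max(0, 1 − y_n w·x_n),

with no intercept by default (the decision rule is sgn(w·x), and sgn(0) = −1
— a zero score is read as "no evidence of causality"). Training delegates to
liblinear via :class:`sklearn.svm.LinearSVC` with hinge loss, which solves
exactly this objective; tests check the returned primal objective against an
independent quadratic-program solution of the dual.

Because the kernel is linear, each learned weight ``w_i`` is directly the
influence of one skip-gram pattern on the causality decision, which is what
makes the model inspectable: top-ranked positive/negative patterns and the
count of exactly-zero weights are first-class outputs.

Model files are plain UTF-8 text — a few header lines, then one
``serialized_pattern<TAB>weight`` line per dimension — and round-trip
predictions bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import csr_matrix, issparse
from sklearn.svm import LinearSVC

from .exceptions import InvalidInputError, ModelFormatError, TrainingError
from .features import FeatureVector, PatternVocabulary, TokenVocabulary, to_csr
from .patterns import parse_pattern

__all__ = [
    "TrainedModel",
    "train_svm",
    "decision_value",
    "predict",
    "predict_matrix",
    "primal_objective",
    "tune_C",
    "top_k_patterns",
    "zero_weight_stats",
    "ZeroWeightStats",
    "save_model",
    "load_model",
]

Matrix = Union[csr_matrix, np.ndarray, Sequence[FeatureVector]]


@dataclass
class TrainedModel:
    """Learned per-pattern weights plus the hyperparameters that produced them."""

    weights: np.ndarray
    C: float
    vocabulary: Optional[Union[PatternVocabulary, TokenVocabulary]] = None
    intercept: Optional[float] = None
    tolerance: float = 1e-6
    feature_config: Dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return int(self.weights.shape[0])


def _as_matrix(X: Matrix) -> Union[csr_matrix, np.ndarray]:
    if issparse(X) or isinstance(X, np.ndarray):
        return X
    return to_csr(list(X))


def train_svm(
    X: Matrix,
    y: Sequence[int],
    C: float = 1.0,
    tolerance: float = 1e-6,
    fit_intercept: bool = False,
    vocabulary: Optional[Union[PatternVocabulary, TokenVocabulary]] = None,
    feature_config: Optional[Dict] = None,
    max_iter: int = 1_000_000,
) -> TrainedModel:
    """Fit the soft-margin linear SVM.

    Raises
    ------
    TrainingError
        If only one class is present.
    InvalidInputError
        If ``C <= 0`` or shapes disagree.
    """
    if not (C > 0):
        raise InvalidInputError(f"C must be positive, got {C!r}")
    Xm = _as_matrix(X)
    yv = np.asarray(list(y), dtype=float)
    if Xm.shape[0] != yv.shape[0]:
        raise InvalidInputError(f"{Xm.shape[0]} rows but {yv.shape[0]} labels")
    if Xm.shape[0] < 2 or len(np.unique(yv)) < 2:
        raise TrainingError("training requires at least two instances with both labels present")
    if not set(np.unique(yv)) <= {-1.0, 1.0}:
        raise InvalidInputError("labels must be -1 or +1")
    clf = LinearSVC(
        C=C,
        loss="hinge",
        penalty="l2",
        dual=True,
        fit_intercept=fit_intercept,
        intercept_scaling=1.0,
        tol=tolerance,
        max_iter=max_iter,
        random_state=0,
    )
    clf.fit(Xm, yv)
    # classes_ is sorted [-1, 1]; coef_ scores the +1 class.
    w = np.array(clf.coef_, dtype=float).ravel().copy()
    b = float(clf.intercept_[0]) if fit_intercept else None
    return TrainedModel(
        weights=w,
        C=float(C),
        vocabulary=vocabulary,
        intercept=b,
        tolerance=float(tolerance),
        feature_config=dict(feature_config or {}),
    )


def decision_value(model: TrainedModel, x: Union[FeatureVector, np.ndarray]) -> float:
    """w·x (+ intercept if enabled), computed with a fixed summation order."""
    if isinstance(x, FeatureVector):
        if x.d != model.d:
            raise InvalidInputError(f"feature vector has d={x.d}, model expects d={model.d}")
        v = float(np.sum(model.weights[np.fromiter(x.active, dtype=np.intp, count=len(x.active))])) if x.active else 0.0
    else:
        xa = np.asarray(x, dtype=float).ravel()
        if xa.shape[0] != model.d:
            raise InvalidInputError(f"input has dimension {xa.shape[0]}, model expects {model.d}")
        v = float(model.weights @ xa)
    if model.intercept is not None:
        v += model.intercept
    return v


def predict(model: TrainedModel, x: Union[FeatureVector, np.ndarray]) -> int:
    """sgn of the decision value with sgn(0) = −1."""
    return 1 if decision_value(model, x) > 0 else -1


def predict_matrix(model: TrainedModel, X: Matrix) -> np.ndarray:
    """Vectorized prediction for a batch; same sign convention as :func:`predict`."""
    Xm = _as_matrix(X)
    if Xm.shape[1] != model.d:
        raise InvalidInputError(f"matrix has {Xm.shape[1]} columns, model expects {model.d}")
    scores = np.asarray(Xm @ model.weights).ravel()
    if model.intercept is not None:
        scores = scores + model.intercept
    return np.where(scores > 0, 1, -1)


def primal_objective(model: TrainedModel, X: Matrix, y: Sequence[int]) -> float:
    """½‖w‖² + C Σ max(0, 1 − y·score) at the model's weights."""
    Xm = _as_matrix(X)
    yv = np.asarray(list(y), dtype=float)
    scores = np.asarray(Xm @ model.weights).ravel()
    if model.intercept is not None:
        scores = scores + model.intercept
    slack = np.maximum(0.0, 1.0 - yv * scores)
    return float(0.5 * model.weights @ model.weights + model.C * slack.sum())


def tune_C(
    train: Tuple[Matrix, Sequence[int]],
    dev: Tuple[Matrix, Sequence[int]],
    grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    tolerance: float = 1e-6,
    fit_intercept: bool = False,
) -> float:
    """Pick the grid C maximizing held-out accuracy; ties go to the smallest C."""
    if len(grid) == 0:
        raise InvalidInputError("C grid is empty")
    if any(not (c > 0) for c in grid):
        raise InvalidInputError("all grid values must be positive")
    Xtr, ytr = train
    Xd, yd = dev
    yd = np.asarray(list(yd), dtype=float)
    best_C, best_acc = None, -1.0
    for c in sorted(grid):
        model = train_svm(Xtr, ytr, C=c, tolerance=tolerance, fit_intercept=fit_intercept)
        acc = float(np.mean(predict_matrix(model, Xd) == yd))
        if acc > best_acc:
            best_C, best_acc = c, acc
    return float(best_C)


def top_k_patterns(model: TrainedModel, k: int, sign: str) -> List[Tuple[str, float]]:
    """The k most positively (sign '+') or negatively ('-') weighted patterns.

    Returned as (serialized pattern, weight), ordered by |weight| descending;
    ``k > d`` simply returns all d entries.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if sign not in ("+", "-"):
        raise InvalidInputError("sign must be '+' or '-'")
    if model.vocabulary is None:
        raise InvalidInputError("model has no vocabulary to name patterns")
    w = model.weights
    order = np.argsort(-w, kind="stable") if sign == "+" else np.argsort(w, kind="stable")
    take = order[: min(k, model.d)]
    return [(model.vocabulary.labels[i], float(w[i])) for i in take]


@dataclass(frozen=True)
class ZeroWeightStats:
    """Count/fraction of (near-)zero weights plus fixed-bin histogram data."""

    count: int
    fraction: float
    tolerance: float
    hist_counts: Tuple[int, ...]
    bin_edges: Tuple[float, ...]


def zero_weight_stats(
    model: TrainedModel, tolerance: float = 1e-12, bins: int = 61
) -> ZeroWeightStats:
    """How many patterns the SVM pruned to (numerically) zero weight."""
    w = model.weights
    count = int(np.sum(np.abs(w) <= tolerance))
    span = max(float(np.max(np.abs(w))) if w.size else 0.0, tolerance)
    counts, edges = np.histogram(w, bins=bins, range=(-span, span))
    return ZeroWeightStats(
        count=count,
        fraction=count / w.size if w.size else 0.0,
        tolerance=tolerance,
        hist_counts=tuple(int(c) for c in counts),
        bin_edges=tuple(float(e) for e in edges),
    )


_MAGIC = "#adrcause-model v1"


def save_model(model: TrainedModel, path) -> None:
    """Write the text model format (header lines, then pattern<TAB>weight)."""
    if model.vocabulary is None or len(model.vocabulary) != model.d:
        raise InvalidInputError("model needs a vocabulary matching its dimensionality to be saved")
    lines = [
        _MAGIC,
        f"#d\t{model.d}",
        f"#C\t{model.C!r}",
        f"#intercept\t{'none' if model.intercept is None else repr(model.intercept)}",
        f"#tolerance\t{model.tolerance!r}",
        f"#features\t{json.dumps(model.feature_config, sort_keys=True)}",
        f"#vocab_sha256\t{model.vocabulary.content_hash()}",
    ]
    for label, wi in zip(model.vocabulary.labels, model.weights):
        lines.append(f"{label}\t{float(wi)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> TrainedModel:
    """Read a model file back; predictions on the same inputs are bit-identical."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ModelFormatError(f"{path}: not an adrcause model file")
    header: Dict[str, str] = {}
    body_start = 1
    for i, line in enumerate(lines[1:], start=1):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line[1:].partition("\t")
        header[key] = val
    else:
        body_start = len(lines)
    try:
        d = int(header["d"])
        C = float(header["C"])
        intercept = None if header["intercept"] == "none" else float(header["intercept"])
        tolerance = float(header["tolerance"])
        feature_config = json.loads(header["features"])
        vocab_hash = header["vocab_sha256"]
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"{path}: bad header ({exc})") from None
    labels: list[str] = []
    weights: list[float] = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line:
            continue
        label, sep, wstr = line.partition("\t")
        if not sep:
            raise ModelFormatError(f"{path}:{lineno}: expected pattern<TAB>weight")
        try:
            weights.append(float(wstr))
        except ValueError:
            raise ModelFormatError(f"{path}:{lineno}: bad weight {wstr!r}") from None
        labels.append(label)
    if len(labels) != d:
        raise ModelFormatError(f"{path}: header says d={d} but found {len(labels)} weight lines")
    if feature_config.get("kind", "pattern") == "bow":
        vocab: Union[PatternVocabulary, TokenVocabulary] = TokenVocabulary(labels)
    else:
        vocab = PatternVocabulary(
            (parse_pattern(s) for s in labels),
            n_max=int(feature_config.get("n_max", 3)),
            max_wildcards=int(feature_config.get("max_wildcards", 1)),
            segments=tuple(feature_config.get("segments", ["P", "M", "S"])),
        )
    if tuple(vocab.labels) != tuple(labels):
        raise ModelFormatError(f"{path}: pattern lines are not in canonical sorted order")
    if vocab.content_hash() != vocab_hash:
        raise ModelFormatError(f"{path}: vocabulary hash mismatch")
    return TrainedModel(
        weights=np.array(weights, dtype=float),
        C=C,
        vocabulary=vocab,
        intercept=intercept,
        tolerance=tolerance,
        feature_config=feature_config,
    )
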