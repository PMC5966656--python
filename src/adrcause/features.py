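"""Pattern vocabularies and boolean feature vectors.

The vocabulary is fixed at fit time from the training posts only; each
distinct skip-gram pattern becomes one boolean dimension. A post's feature
vector has a 1 exactly where a vocabulary pattern matches its segmentation
(equivalently: where the pattern is in the post's extracted set — extraction
enumerates every matching pattern). Patterns seen only at test time are
silently dropped, so the dimensionality never grows after fitting.

A parallel unigram-presence vocabulary supports the bag-of-words baseline;
entity tokens are excluded there too, for comparability.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple, Union

from scipy.sparse import csr_matrix

from .exceptions import InvalidInputError
from .patterns import (
    SEGMENT_TAGS,
    SkipGramPattern,
    extract_post_patterns,
    serialize_pattern,
)
from .segmentation import AnnotatedPost, Segmentation, segment_post

__all__ = [
    "FeatureVector",
    "PatternVocabulary",
    "TokenVocabulary",
    "fit_vocabulary",
    "vectorize",
    "bow_token_set",
    "fit_bow_vocabulary",
    "bow_vectorize",
    "to_csr",
]


@dataclass(frozen=True)
class FeatureVector:
    """Sparse boolean vector: dimension ``d`` plus the sorted active indices."""

    d: int
    active: Tuple[int, ...]

    def __post_init__(self) -> None:
        if any(not (0 <= i < self.d) for i in self.active):
            raise InvalidInputError("active indices out of range")


class PatternVocabulary:
    """Bijection between skip-gram patterns and feature dimensions.

    Patterns are ordered lexicographically on their serialized form, so the
    dimensionality and index assignment are reproducible across runs. The
    extraction parameters used at fit time travel with the vocabulary so
    vectorization is self-contained.
    """

    def __init__(
        self,
        patterns: Iterable[SkipGramPattern],
        n_max: int = 3,
        max_wildcards: int = 1,
        segments: Tuple[str, ...] = SEGMENT_TAGS,
    ) -> None:
        by_label = {serialize_pattern(p): p for p in patterns}
        self.labels: Tuple[str, ...] = tuple(sorted(by_label))
        self.patterns: Tuple[SkipGramPattern, ...] = tuple(by_label[s] for s in self.labels)
        self._index = {p: i for i, p in enumerate(self.patterns)}
        self.n_max = n_max
        self.max_wildcards = max_wildcards
        self.segments = tuple(segments)

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, p: SkipGramPattern) -> bool:
        return p in self._index

    def __iter__(self):
        return iter(self.patterns)

    def index_of(self, p: SkipGramPattern) -> int:
        return self._index[p]

    def content_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.labels).encode("utf-8"))
        return h.hexdigest()


class TokenVocabulary:
    """Unigram vocabulary for the bag-of-words baseline (sorted, stable)."""

    def __init__(self, tokens: Iterable[str]) -> None:
        self.labels: Tuple[str, ...] = tuple(sorted(set(tokens)))
        self._index = {t: i for i, t in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, tok: str) -> bool:
        return tok in self._index

    def index_of(self, tok: str) -> int:
        return self._index[tok]

    def content_hash(self) -> str:
        return hashlib.sha256("\n".join(self.labels).encode("utf-8")).hexdigest()


def _as_segmentation(post: Union[AnnotatedPost, Segmentation]) -> Segmentation:
    return post if isinstance(post, Segmentation) else segment_post(post)


def fit_vocabulary(
    training_posts: Sequence[AnnotatedPost],
    n_max: int = 3,
    max_wildcards: int = 1,
    min_frequency: int = 1,
    segments: Tuple[str, ...] = SEGMENT_TAGS,
) -> PatternVocabulary:
    """Build the pattern vocabulary from the training posts.

    ``min_frequency`` is a document-frequency floor: a pattern is kept only if
    it occurs in at least that many distinct posts (default 1 = keep all).
    """
    if len(training_posts) == 0:
        raise InvalidInputError("training set is empty")
    if min_frequency < 1:
        raise InvalidInputError("min_frequency must be >= 1")
    df: dict[SkipGramPattern, int] = {}
    for post in training_posts:
        for p in extract_post_patterns(_as_segmentation(post), n_max, max_wildcards, segments):
            df[p] = df.get(p, 0) + 1
    kept = (p for p, c in df.items() if c >= min_frequency)
    return PatternVocabulary(kept, n_max=n_max, max_wildcards=max_wildcards, segments=segments)


def vectorize(post: Union[AnnotatedPost, Segmentation], vocab: PatternVocabulary) -> FeatureVector:
    """Boolean feature vector of ``post`` under a fitted vocabulary."""
    pats = extract_post_patterns(
        _as_segmentation(post), vocab.n_max, vocab.max_wildcards, vocab.segments
    )
    active = sorted(vocab.index_of(p) for p in pats if p in vocab)
    return FeatureVector(d=len(vocab), active=tuple(active))


def bow_token_set(post: Union[AnnotatedPost, Segmentation]) -> Set[str]:
    """Distinct non-entity tokens of the post (order-free unigram presence)."""
    seg = _as_segmentation(post)
    return set(seg.prefix_tokens) | set(seg.midfix_tokens) | set(seg.postfix_tokens)


def fit_bow_vocabulary(training_posts: Sequence[AnnotatedPost]) -> TokenVocabulary:
    if len(training_posts) == 0:
        raise InvalidInputError("training set is empty")
    toks: Set[str] = set()
    for post in training_posts:
        toks |= bow_token_set(post)
    return TokenVocabulary(toks)


def bow_vectorize(post: Union[AnnotatedPost, Segmentation], vocab: TokenVocabulary) -> FeatureVector:
    active = sorted(vocab.index_of(t) for t in bow_token_set(post) if t in vocab)
    return FeatureVector(d=len(vocab), active=tuple(active))


def to_csr(vectors: Sequence[FeatureVector]) -> csr_matrix:
    """Stack boolean feature vectors into a CSR matrix of 0/1 floats."""
    if len(vectors) == 0:
        raise InvalidInputError("no feature vectors to stack")
    d = vectors[0].d
    if any(v.d != d for v in vectors):
        raise InvalidInputError("feature vectors have inconsistent dimensionality")
    indptr = [0]
    indices: list[int] = []
    for v in vectors:
        indices.extend(v.active)
        indptr.append(len(indices))
    data = [1.0] * len(indices)
    return csr_matrix((data, indices, indptr), shape=(len(vectors), d))
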