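"""Skip-gram lexical pattern extraction, matching and serialization.

A *skip-gram lexical pattern* is a contiguous n-gram (n ∈ {1, 2, 3} by
default) drawn from one of the three entity contexts, in which at most one
position may be the wildcard ``*`` that matches any single token. Wildcards
subsume the plain n-grams: ``* ago`` generalizes ``while ago`` and also
matches ``hours ago`` or ``days ago``. Patterns are tagged with their source
segment (P = prefix, M = midfix, S = postfix), so the same token sequence
occurring in two segments yields two distinct features.

The wildcard is a dedicated sentinel object, not the string ``"*"``: a
literal asterisk token in text (detached punctuation) therefore never
collides with the wildcard, and serialization escapes it.

Serialized form is the ``TAG+tok+tok`` convention, e.g. ``M+*+ago`` or
``P+took+too``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple, Union

from .exceptions import InvalidInputError, PatternError
from .segmentation import Segmentation

__all__ = [
    "WILDCARD",
    "SEGMENT_TAGS",
    "SkipGramPattern",
    "extract_ngrams",
    "extract_skipgrams",
    "extract_post_patterns",
    "pattern_matches",
    "serialize_pattern",
    "parse_pattern",
]

SEGMENT_TAGS = ("P", "M", "S")


class _WildcardType:
    """Singleton marker for the any-token wildcard position."""

    _instance = None

    def __new__(cls) -> "_WildcardType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "*"

    def __reduce__(self):
        return (_WildcardType, ())


WILDCARD = _WildcardType()

PatternItem = Union[str, _WildcardType]


@dataclass(frozen=True)
class SkipGramPattern:
    """A segment-tagged token sequence with at most one wildcard position."""

    segment_tag: str
    tokens: Tuple[PatternItem, ...]

    def __post_init__(self) -> None:
        if self.segment_tag not in SEGMENT_TAGS:
            raise PatternError(f"segment_tag must be one of {SEGMENT_TAGS}, got {self.segment_tag!r}")
        if not isinstance(self.tokens, tuple) or len(self.tokens) < 1:
            raise PatternError("tokens must be a non-empty tuple")
        n_wild = 0
        for item in self.tokens:
            if isinstance(item, _WildcardType):
                n_wild += 1
            elif not (isinstance(item, str) and item):
                raise PatternError(f"pattern item must be a non-empty string or WILDCARD, got {item!r}")
        if n_wild > 1:
            raise PatternError("at most one wildcard is allowed in a pattern")
        if n_wild == 1 and len(self.tokens) == 1:
            raise PatternError("a unigram pattern must not be the bare wildcard")

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def has_wildcard(self) -> bool:
        return any(isinstance(item, _WildcardType) for item in self.tokens)

    def __str__(self) -> str:
        return serialize_pattern(self)


def _check_n(n: int) -> None:
    if not isinstance(n, int) or n < 1:
        raise InvalidInputError(f"n must be a positive integer, got {n!r}")


def extract_ngrams(tokens: Sequence[str], n: int) -> Set[Tuple[str, ...]]:
    """All distinct contiguous windows of length ``n`` (empty set if too short)."""
    _check_n(n)
    toks = tuple(tokens)
    return {toks[i : i + n] for i in range(len(toks) - n + 1)}


def extract_skipgrams(
    tokens: Sequence[str], n: int, max_wildcards: int = 1
) -> Set[Tuple[PatternItem, ...]]:
    """Distinct n-grams plus single-wildcard variants of each window.

    For ``n == 1`` only exact unigrams are produced (the bare wildcard would
    match every post and carry no information). For ``n >= 2`` every window
    additionally contributes one variant per position with that position
    replaced by :data:`WILDCARD`.
    """
    _check_n(n)
    if max_wildcards not in (0, 1):
        raise InvalidInputError(f"max_wildcards must be 0 or 1, got {max_wildcards!r}")
    toks = tuple(tokens)
    out: Set[Tuple[PatternItem, ...]] = set()
    for i in range(len(toks) - n + 1):
        window = toks[i : i + n]
        out.add(window)
        if max_wildcards == 1 and n >= 2:
            for j in range(n):
                out.add(window[:j] + (WILDCARD,) + window[j + 1 :])
    return out


def extract_post_patterns(
    seg: Segmentation,
    n_max: int = 3,
    max_wildcards: int = 1,
    segments: Iterable[str] = SEGMENT_TAGS,
) -> Set[SkipGramPattern]:
    """Union of tagged skip-grams over the requested segments and n = 1..n_max."""
    _check_n(n_max)
    out: Set[SkipGramPattern] = set()
    for tag in segments:
        toks = seg.segment(tag)
        for n in range(1, n_max + 1):
            for pat in extract_skipgrams(toks, n, max_wildcards):
                out.add(SkipGramPattern(tag, pat))
    return out


def pattern_matches(p: SkipGramPattern, seg: Segmentation) -> bool:
    """True iff some window of the pattern's segment matches it position-wise."""
    toks = seg.segment(p.segment_tag)
    n = p.n
    for i in range(len(toks) - n + 1):
        if all(
            isinstance(item, _WildcardType) or item == toks[i + j]
            for j, item in enumerate(p.tokens)
        ):
            return True
    return False


def _escape(tok: str) -> str:
    return tok.replace("\\", "\\\\").replace("+", "\\+").replace("*", "\\*")


def serialize_pattern(p: SkipGramPattern) -> str:
    """Render ``TAG+tok1+tok2+...`` with the wildcard as a bare ``*``."""
    parts = [
        "*" if isinstance(item, _WildcardType) else _escape(item) for item in p.tokens
    ]
    return p.segment_tag + "+" + "+".join(parts)


def parse_pattern(s: str) -> SkipGramPattern:
    """Inverse of :func:`serialize_pattern`; raises :class:`PatternError` on bad input."""
    if not isinstance(s, str) or len(s) < 3 or s[0] not in SEGMENT_TAGS or s[1] != "+":
        raise PatternError(f"malformed pattern string {s!r}")
    body = s[2:]
    raw_parts: list[list[tuple[str, bool]]] = [[]]  # (char, was_escaped)
    i = 0
    while i < len(body):
        c = body[i]
        if c == "\\":
            if i + 1 >= len(body):
                raise PatternError(f"dangling escape in {s!r}")
            raw_parts[-1].append((body[i + 1], True))
            i += 2
        elif c == "+":
            raw_parts.append([])
            i += 1
        else:
            raw_parts[-1].append((c, False))
            i += 1
    items: list[PatternItem] = []
    for part in raw_parts:
        if not part:
            raise PatternError(f"empty token in pattern string {s!r}")
        if len(part) == 1 and part[0] == ("*", False):
            items.append(WILDCARD)
        else:
            items.append("".join(ch for ch, _ in part))
    try:
        return SkipGramPattern(s[0], tuple(items))
    except PatternError as exc:
        raise PatternError(f"invalid pattern {s!r}: {exc}") from None
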