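"""Text normalization and entity-context segmentation.

A post mentions exactly one drug and one event, each as a character span.
The token stream is split into three contexts around the two entities:

* **prefix** — tokens strictly before the first-mentioned entity,
* **midfix** — tokens strictly between the two entities,
* **postfix** — tokens strictly after the second-mentioned entity.

The entity tokens themselves belong to none of the three contexts, so the
patterns extracted downstream generalize over drug and event surface forms.

Tokenization is deliberately simple and reproducible: lowercase, split on
whitespace, and detach leading/trailing punctuation into single-character
tokens while keeping apostrophes word-internal (so ``i'm`` stays one token but
``news:`` becomes ``news`` ``:``). Every token carries its source character
interval so entity spans can be mapped onto token positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

from .exceptions import InvalidInputError, SegmentationError

__all__ = [
    "Token",
    "AnnotatedPost",
    "Segmentation",
    "normalize_text",
    "segment_post",
]

_APOSTROPHES = frozenset({"'", "’"})
_WS = re.compile(r"\S+")


@dataclass(frozen=True)
class Token:
    """A lowercased token with its half-open character interval in the raw text."""

    text: str
    start: int
    end: int


def _is_detachable(ch: str) -> bool:
    return not (ch.isalnum() or ch in _APOSTROPHES)


def normalize_text(raw: str) -> list[Token]:
    """Tokenize ``raw`` into lowercased, alignment-preserving tokens.

    Punctuation at the edge of a whitespace-delimited chunk becomes its own
    single-character token; word-internal punctuation and apostrophes are kept.

    Raises
    ------
    InvalidInputError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidInputError("post text is empty or whitespace-only")
    tokens: list[Token] = []
    for m in _WS.finditer(raw):
        chunk, off = m.group(), m.start()
        a, b = 0, len(chunk)
        lead: list[int] = []
        while a < b and _is_detachable(chunk[a]):
            lead.append(a)
            a += 1
        trail: list[int] = []
        while b > a and _is_detachable(chunk[b - 1]):
            b -= 1
            trail.append(b)
        for i in lead:
            tokens.append(Token(chunk[i].lower(), off + i, off + i + 1))
        if a < b:
            tokens.append(Token(chunk[a:b].lower(), off + a, off + b))
        for i in sorted(trail):
            tokens.append(Token(chunk[i].lower(), off + i, off + i + 1))
    return tokens


@dataclass(frozen=True)
class AnnotatedPost:
    """One social-media post with one drug span, one event span and a label.

    Spans are 0-based half-open character intervals into ``text``. ``label``
    is +1 when the post asserts the event was caused by the drug, −1 when not,
    and ``None`` at prediction time.
    """

    id: str
    text: str
    drug_span: Tuple[int, int]
    event_span: Tuple[int, int]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.text)
        for name, (s, e) in (("drug_span", self.drug_span), ("event_span", self.event_span)):
            if not (isinstance(s, int) and isinstance(e, int) and 0 <= s < e <= n):
                raise InvalidInputError(
                    f"{name}={s, e} is not a valid interval into text of length {n}"
                )
        d0, d1 = self.drug_span
        e0, e1 = self.event_span
        if d0 < e1 and e0 < d1:
            raise InvalidInputError(
                f"drug_span {self.drug_span} overlaps event_span {self.event_span}"
            )
        if self.label is not None and self.label not in (-1, 1):
            raise InvalidInputError(f"label must be -1, +1 or None, got {self.label!r}")


@dataclass(frozen=True)
class Segmentation:
    """Prefix/midfix/postfix token contexts around the two entity mentions.

    ``drug_first`` records whether the drug span precedes the event span;
    swapping which entity is the drug leaves the three contexts unchanged and
    flips only this flag. ``entity1_tokens``/``entity2_tokens`` hold the tokens
    covered by the first- and second-mentioned entity spans (kept for
    round-trip checks; they never enter pattern extraction).
    """

    prefix_tokens: Tuple[str, ...]
    midfix_tokens: Tuple[str, ...]
    postfix_tokens: Tuple[str, ...]
    drug_first: bool
    entity1_tokens: Tuple[str, ...] = ()
    entity2_tokens: Tuple[str, ...] = ()

    def segment(self, tag: str) -> Tuple[str, ...]:
        """Return the token tuple for segment tag ``"P"``, ``"M"`` or ``"S"``."""
        try:
            return {
                "P": self.prefix_tokens,
                "M": self.midfix_tokens,
                "S": self.postfix_tokens,
            }[tag]
        except KeyError:
            raise InvalidInputError(f"unknown segment tag {tag!r}") from None


def segment_post(post: AnnotatedPost) -> Segmentation:
    """Split ``post`` into prefix, midfix and postfix token contexts.

    Entity spans must align to token boundaries of the normalized text: every
    token overlapping a span must lie fully inside it.

    Raises
    ------
    SegmentationError
        If a span covers no token or cuts through a token.
    """
    tokens = normalize_text(post.text)
    spans = sorted(
        (("drug", post.drug_span), ("event", post.event_span)), key=lambda kv: kv[1][0]
    )
    entity_indices: list[list[int]] = []
    for name, (s, e) in spans:
        idx = [i for i, t in enumerate(tokens) if t.start < e and t.end > s]
        if not idx:
            raise SegmentationError(f"{name} span ({s}, {e}) covers no token")
        for i in idx:
            if tokens[i].start < s or tokens[i].end > e:
                raise SegmentationError(
                    f"{name} span ({s}, {e}) is not aligned to token boundaries "
                    f"(cuts token {tokens[i].text!r} at ({tokens[i].start}, {tokens[i].end}))"
                )
        entity_indices.append(idx)
    first, second = entity_indices
    return Segmentation(
        prefix_tokens=tuple(t.text for t in tokens[: first[0]]),
        midfix_tokens=tuple(t.text for t in tokens[first[-1] + 1 : second[0]]),
        postfix_tokens=tuple(t.text for t in tokens[second[-1] + 1 :]),
        drug_first=spans[0][0] == "drug",
        entity1_tokens=tuple(tokens[i].text for i in first),
        entity2_tokens=tuple(tokens[i].text for i in second),
    )
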