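"""Seeded synthetic annotated-post corpora.

The real study corpus (tens of thousands of manually annotated tweets) is
private, so this module generates labeled posts with the statistical
structure the method assumes: each post is a tweet-length text containing
exactly one drug mention and one event mention, and the causality label is
signalled by class-specific cue phrases placed in the three entity contexts.

The generative process per post:

1. draw the label from the configured class balance (default 47.2% positive,
   echoing a realistic pharmacovigilance stream where most drug–event
   co-mentions are not causal);
2. draw the entity order (drug-first vs event-first) uniformly;
3. for each of prefix/midfix/postfix, draw 0–3 filler tokens from a small
   class-independent vocabulary, then with the segment's cue-injection
   probability insert one cue phrase from the label's lexicon for that
   segment (default probabilities make the midfix the most informative
   context, so segment-ablation experiments have a planted ordering);
4. assemble the text, recording exact character spans for both entities;
   filler tokens are dropped (never cue tokens) if the post would exceed the
   length cap.

Positive and negative cue lexicons share no tokens and fillers overlap
neither, so the Bayes-optimal accuracy of the process is available in closed
form: a post is perfectly classifiable iff at least one cue was injected,
otherwise the best guess is the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple, Union

import numpy as np

from .exceptions import GenerationError, InvalidInputError
from .patterns import SkipGramPattern
from .segmentation import AnnotatedPost

__all__ = [
    "SyntheticConfig",
    "generate_corpus",
    "oracle_accuracy",
    "planted_cue_patterns",
    "DEFAULT_POSITIVE_CUES",
    "DEFAULT_NEGATIVE_CUES",
]

DEFAULT_DRUGS = ("atenolol", "ibuprofen", "xanax", "tramadol", "metformin", "sertraline")
DEFAULT_EVENTS = ("dizziness", "headache", "nausea", "insomnia", "rash", "fatigue")

# Cue lexicons follow the qualitative flavour of real causal/non-causal posts:
# first-person intake markers and causal verbs for positives; advertising,
# hedging and negation markers for negatives. Token sets of the two classes
# are disjoint (and disjoint from the fillers) so the Bayes rate is exact.
DEFAULT_POSITIVE_CUES: Dict[str, Tuple[Tuple[str, ...], ...]] = {
    "P": (("took",), ("high", "off")),
    "M": (("induced",), ("now", "feeling")),
    "S": (("worst", "ever"), ("feels", "horrible")),
}
DEFAULT_NEGATIVE_CUES: Dict[str, Tuple[Tuple[str, ...], ...]] = {
    "P": (("hate", "being"), ("don't", "think")),
    "M": (("commercial",), ("not", "because")),
    "S": (("lol", "fml"), ("no", "way")),
}

DEFAULT_FILLERS = (
    "the", "a", "my", "to", "it", "on", "for", "with", "at", "this",
    "that", "today", "morning", "coffee", "work", "again", "stuff",
    "thing", "really", "just",
)

_TAGS = ("P", "M", "S")


@dataclass
class SyntheticConfig:
    """All knobs of the generative process, with study-condition defaults."""

    n_posts: int = 5000
    positive_fraction: float = 0.472
    cue_injection_prob: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"P": 0.4, "M": 0.7, "S": 0.4}
    )
    positive_cues: Dict[str, Tuple[Tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_CUES)
    )
    negative_cues: Dict[str, Tuple[Tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_NEGATIVE_CUES)
    )
    filler_vocab: Tuple[str, ...] = DEFAULT_FILLERS
    max_fillers_per_segment: int = 3
    max_length: int = 140
    drug_names: Tuple[str, ...] = DEFAULT_DRUGS
    event_names: Tuple[str, ...] = DEFAULT_EVENTS
    seed: int = 0

    def injection_probs(self) -> Dict[str, float]:
        p = self.cue_injection_prob
        if isinstance(p, Mapping):
            return {t: float(p[t]) for t in _TAGS}
        return {t: float(p) for t in _TAGS}

    def validate(self) -> None:
        if self.n_posts < 1:
            raise InvalidInputError("n_posts must be >= 1")
        if not (0.0 < self.positive_fraction < 1.0):
            raise InvalidInputError("positive_fraction must lie in (0, 1)")
        probs = self.injection_probs()
        for t, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise InvalidInputError(f"cue_injection_prob[{t}] = {p} out of [0, 1]")
            if p > 0:
                for cues in (self.positive_cues, self.negative_cues):
                    if not cues.get(t):
                        raise InvalidInputError(
                            f"segment {t} has injection prob {p} but no cue templates"
                        )
        if not self.filler_vocab and self.max_fillers_per_segment > 0:
            raise InvalidInputError("filler_vocab is empty")
        if not self.drug_names or not self.event_names:
            raise InvalidInputError("drug_names and event_names must be non-empty")
        if self.max_length < 20:
            raise InvalidInputError("max_length too small to hold two entities")


def _draw_segment(
    rng: np.random.Generator,
    config: SyntheticConfig,
    cues: Dict[str, Tuple[Tuple[str, ...], ...]],
    tag: str,
    p_inject: float,
) -> List[Tuple[str, bool]]:
    """Tokens of one segment as (token, is_filler) pairs."""
    k = int(rng.integers(0, config.max_fillers_per_segment + 1))
    toks: List[Tuple[str, bool]] = [
        (config.filler_vocab[int(rng.integers(len(config.filler_vocab)))], True)
        for _ in range(k)
    ]
    if p_inject > 0 and rng.random() < p_inject:
        phrase = cues[tag][int(rng.integers(len(cues[tag])))]
        at = int(rng.integers(0, len(toks) + 1))
        toks[at:at] = [(t, False) for t in phrase]
    return toks


def _assemble(
    segs: Dict[str, List[Tuple[str, bool]]], ent1: str, ent2: str
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    words = (
        [t for t, _ in segs["P"]] + [ent1] + [t for t, _ in segs["M"]] + [ent2] + [t for t, _ in segs["S"]]
    )
    text = " ".join(words)
    off = 0
    span1 = span2 = None
    i_ent1 = len(segs["P"])
    i_ent2 = i_ent1 + 1 + len(segs["M"])
    for i, w in enumerate(words):
        if i == i_ent1:
            span1 = (off, off + len(w))
        elif i == i_ent2:
            span2 = (off, off + len(w))
        off += len(w) + 1
    return text, span1, span2


def generate_corpus(config: SyntheticConfig) -> List[AnnotatedPost]:
    """Generate a labeled corpus; byte-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = config.injection_probs()
    n_pos = int(round(config.n_posts * config.positive_fraction))
    labels = np.array([1] * n_pos + [-1] * (config.n_posts - n_pos))
    rng.shuffle(labels)
    posts: List[AnnotatedPost] = []
    for i, lab in enumerate(labels):
        cues = config.positive_cues if lab == 1 else config.negative_cues
        segs = {t: _draw_segment(rng, config, cues, t, probs[t]) for t in _TAGS}
        drug = config.drug_names[int(rng.integers(len(config.drug_names)))]
        event = config.event_names[int(rng.integers(len(config.event_names)))]
        drug_first = bool(rng.random() < 0.5)
        ent1, ent2 = (drug, event) if drug_first else (event, drug)
        text, span1, span2 = _assemble(segs, ent1, ent2)
        # Shed fillers (never cue tokens) from the back until the length cap fits.
        while len(text) > config.max_length:
            for t in ("S", "M", "P"):
                filler_pos = [j for j, (_, isf) in enumerate(segs[t]) if isf]
                if filler_pos:
                    del segs[t][filler_pos[-1]]
                    break
            else:
                raise GenerationError(
                    f"post {i} cannot fit within max_length={config.max_length}"
                )
            text, span1, span2 = _assemble(segs, ent1, ent2)
        drug_span, event_span = (span1, span2) if drug_first else (span2, span1)
        posts.append(
            AnnotatedPost(
                id=f"synt{i:05d}",
                text=text,
                drug_span=drug_span,
                event_span=event_span,
                label=int(lab),
            )
        )
    return posts


def oracle_accuracy(config: SyntheticConfig) -> float:
    """Bayes-optimal accuracy (%) implied by the generative process.

    A post is perfectly classifiable iff at least one segment received a cue
    (cue lexicons are class-disjoint); otherwise the optimal rule predicts the
    majority class. Injection is independent per segment, identically for both
    classes, so

        P(any cue) = 1 − ∏_seg (1 − p_seg)
        Bayes accuracy = P(any cue) + (1 − P(any cue)) · max(q, 1 − q).
    """
    config.validate()
    probs = config.injection_probs()
    p_none = float(np.prod([1.0 - probs[t] for t in _TAGS]))
    q = config.positive_fraction
    return 100.0 * ((1.0 - p_none) + p_none * max(q, 1.0 - q))


def planted_cue_patterns(config: SyntheticConfig) -> List[Tuple[SkipGramPattern, int]]:
    """The exact n-gram patterns planted by the generator, with their class sign.

    These are the patterns a faithful learner should recover: positive-cue
    patterns with positive SVM weight, negative-cue patterns with negative.
    """
    out: List[Tuple[SkipGramPattern, int]] = []
    for sign, cues in ((1, config.positive_cues), (-1, config.negative_cues)):
        for tag in _TAGS:
            for phrase in cues.get(tag, ()):
                out.append((SkipGramPattern(tag, tuple(phrase)), sign))
    return out
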