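"""Skip-gram extraction, matching and the TAG+tok+tok serialization."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from adrcause import (
    WILDCARD,
    AnnotatedPost,
    InvalidInputError,
    PatternError,
    SkipGramPattern,
    extract_ngrams,
    extract_post_patterns,
    extract_skipgrams,
    parse_pattern,
    pattern_matches,
    segment_post,
    serialize_pattern,
)
from adrcause.segmentation import Segmentation

from oracles import ngrams_bruteforce, skipgrams_bruteforce

TOKEN = st.text(alphabet="abcde", min_size=1, max_size=3)


def test_midfix_trigrams_of_worked_example():
    tokens = ["while", "ago", "and", "now", "feeling", "very"]
    assert extract_ngrams(tokens, 3) == {
        ("while", "ago", "and"),
        ("ago", "and", "now"),
        ("and", "now", "feeling"),
        ("now", "feeling", "very"),
    }


def test_ngrams_empty_when_window_exceeds_length():
    assert extract_ngrams(["a", "b"], 3) == set()


def test_ngram_count_on_distinct_tokens():
    tokens = [f"t{i}" for i in range(9)]
    for n in (1, 2, 3):
        assert len(extract_ngrams(tokens, n)) == len(tokens) - n + 1


def test_invalid_n_rejected():
    with pytest.raises(InvalidInputError):
        extract_ngrams(["a"], 0)
    with pytest.raises(InvalidInputError):
        extract_skipgrams(["a"], 2, max_wildcards=2)


def test_skipgram_bigrams_of_three_distinct_tokens():
    got = extract_skipgrams(["a", "b", "c"], 2)
    assert got == {
        ("a", "b"), ("b", "c"),
        (WILDCARD, "b"), ("a", WILDCARD),
        (WILDCARD, "c"), ("b", WILDCARD),
    }
    assert len(got) == 6


def test_unigram_skipgrams_have_no_wildcard():
    got = extract_skipgrams(["a", "b"], 1)
    assert got == {("a",), ("b",)}


@given(tokens=st.lists(TOKEN, max_size=10), n=st.integers(1, 3))
def test_skipgrams_subsume_ngrams_and_match_bruteforce(tokens, n):
    got = extract_skipgrams(tokens, n)
    assert extract_ngrams(tokens, n) <= got
    assert got == skipgrams_bruteforce(tokens, n)


def test_skipgram_count_law_distinct_tokens():
    """(L−n+1)(n+1) patterns for n ≥ 2 when all tokens differ (no dedup)."""
    tokens = [f"w{i}" for i in range(8)]
    for n in (2, 3):
        assert len(extract_skipgrams(tokens, n)) == (len(tokens) - n + 1) * (n + 1)


@given(tokens=st.lists(TOKEN, max_size=8), extra=TOKEN, n=st.integers(1, 3))
def test_extraction_monotone_in_tokens(tokens, extra, n):
    assert extract_skipgrams(tokens, n) <= extract_skipgrams(tokens + [extra], n)


def _seg(prefix=(), midfix=(), postfix=()):
    return Segmentation(tuple(prefix), tuple(midfix), tuple(postfix), True)


def test_post_patterns_tag_segments_distinctly():
    seg = _seg(prefix=("x", "y"), postfix=("x", "y"))
    pats = extract_post_patterns(seg, n_max=2)
    tags = {p.segment_tag for p in pats}
    assert tags == {"P", "S"}
    p_side = {p.tokens for p in pats if p.segment_tag == "P"}
    s_side = {p.tokens for p in pats if p.segment_tag == "S"}
    assert p_side == s_side  # same token content, distinct patterns via tags


def test_post_patterns_empty_segmentation():
    assert extract_post_patterns(_seg()) == set()


def test_post_pattern_count_matches_enumeration(fig_post):
    seg = segment_post(fig_post)
    expected = 0
    seen = set()
    for tag, toks in (("P", seg.prefix_tokens), ("M", seg.midfix_tokens), ("S", seg.postfix_tokens)):
        for n in (1, 2, 3):
            for pat in skipgrams_bruteforce(toks, n):
                seen.add((tag, pat))
    assert len(extract_post_patterns(seg)) == len(seen)


def test_every_extracted_pattern_matches_its_source(fig_post):
    seg = segment_post(fig_post)
    for p in extract_post_patterns(seg):
        assert pattern_matches(p, seg)


def test_wildcard_matches_any_single_token():
    p = SkipGramPattern("M", (WILDCARD, "ago"))
    assert pattern_matches(p, _seg(midfix=("hours", "ago")))
    assert pattern_matches(p, _seg(midfix=("days", "ago")))
    assert not pattern_matches(p, _seg(midfix=("ago",)))  # no length-2 window
    assert not pattern_matches(p, _seg(prefix=("hours", "ago")))  # wrong segment


def test_pattern_invariants_enforced():
    with pytest.raises(PatternError):
        SkipGramPattern("M", (WILDCARD,))  # bare wildcard unigram
    with pytest.raises(PatternError):
        SkipGramPattern("M", (WILDCARD, WILDCARD))  # two wildcards
    with pytest.raises(PatternError):
        SkipGramPattern("X", ("a",))  # bad tag


@pytest.mark.parametrize(
    "pattern, expected",
    [
        (SkipGramPattern("P", ("took", "too")), "P+took+too"),
        (SkipGramPattern("M", ("induced",)), "M+induced"),
        (SkipGramPattern("M", (WILDCARD, "ago")), "M+*+ago"),
        (SkipGramPattern("S", ("a+b", "*")), "S+a\\+b+\\*"),
    ],
)
def test_serialization_format(pattern, expected):
    assert serialize_pattern(pattern) == expected
    assert parse_pattern(expected) == pattern


@given(
    tag=st.sampled_from("PMS"),
    tokens=st.lists(st.text(alphabet="ab+*\\'", min_size=1, max_size=4), min_size=1, max_size=3),
    wild_at=st.integers(-1, 2),
)
def test_serialize_parse_roundtrip(tag, tokens, wild_at):
    items = list(tokens)
    if 0 <= wild_at < len(items) and len(items) > 1:
        items[wild_at] = WILDCARD
    p = SkipGramPattern(tag, tuple(items))
    assert parse_pattern(serialize_pattern(p)) == p


@pytest.mark.parametrize("bad", ["", "Q+a", "P", "P+", "P+a+", "P+*", "M+a+\\"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(PatternError):
        parse_pattern(bad)
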