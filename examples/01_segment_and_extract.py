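"""Segment an annotated post and enumerate its skip-gram lexical patterns.

A post carries one drug span and one event span. The text splits into
prefix / midfix / postfix contexts around the two entities, and each context
contributes n-grams (n = 1..3) plus single-wildcard variants as features.
"""

from adrcause import AnnotatedPost, extract_post_patterns, segment_post, serialize_pattern

text = "Took Atenolol a while ago and now feeling very dizzy"
post = AnnotatedPost(
    id="example",
    text=text,
    drug_span=(text.index("Atenolol"), text.index("Atenolol") + len("Atenolol")),
    event_span=(text.index("dizzy"), text.index("dizzy") + len("dizzy")),
    label=+1,
)

seg = segment_post(post)
print("prefix: ", seg.prefix_tokens)
print("midfix: ", seg.midfix_tokens)
print("postfix:", seg.postfix_tokens)

patterns = sorted(serialize_pattern(p) for p in extract_post_patterns(seg))
print(f"\n{len(patterns)} distinct patterns; a sample:")
for s in patterns[:6] + patterns[-4:]:
    print(" ", s)

# Each serialized pattern reads TAG+token+token: P/M/S names the context,
# '*' matches any single token. "M+*+ago" generalizes "a while ago",
# "hours ago", "days ago" — one feature covering many phrasings.
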