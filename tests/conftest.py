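import pytest
from hypothesis import HealthCheck, settings

from adrcause import AnnotatedPost, SyntheticConfig, generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig_post():
    """The worked-example post: drug-first, empty postfix."""
    text = "Took Atenolol a while ago and now feeling very dizzy"
    return AnnotatedPost(
        id="fig",
        text=text,
        drug_span=(text.index("Atenolol"), text.index("Atenolol") + len("Atenolol")),
        event_span=(text.index("dizzy"), text.index("dizzy") + len("dizzy")),
        label=1,
    )


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SyntheticConfig(n_posts=120, seed=11))
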