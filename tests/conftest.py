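import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_lexicon():
    from drugchatter import DrugLexicon

    return DrugLexicon(
        canonical={"adderall", "xanax", "seroquel"},
        variants={"adderall": {"adderal", "aderall"}, "seroquel": {"seroquell"}},
    )


@pytest.fixture
def tiny_token_corpus():
    """Deterministic toy corpus over a 5-token vocabulary."""
    return [
        ["a", "b", "a", "c"],
        ["b", "c", "a"],
        ["a", "a", "b", "d"],
        ["c", "d", "e", "a"],
        ["e", "b"],
    ]
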