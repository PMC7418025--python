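import pytest

from tnorm import GenConfig, default_lexicons, generate

# The annotated sentence used throughout to calibrate the pattern miner.
WORKED_SENTENCE = (
    '遂于<TIMEX3 tid="t9" Type="DATE" Value="2014-09-22" anchorTimeID="t3">'
    "22/9</TIMEX3>行右乳癌改良根治术"
)


@pytest.fixture(scope="session")
def worked_sentence() -> str:
    return WORKED_SENTENCE


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def clean_docs():
    """Small noise-free synthetic corpus shared across tests."""
    return generate(GenConfig(n_docs=30, seed=11, typo_rate=0.0, planted_pattern_rate=0.0))


@pytest.fixture(scope="session")
def planted_docs():
    """Corpus where half the documents carry an anchor-equal planted context."""
    return generate(GenConfig(n_docs=30, seed=13, typo_rate=0.0, planted_pattern_rate=0.5))
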