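"""Learn normalization-correction context patterns from annotated text.

First enumerates the candidate templates of a single annotated sentence
(two left-context and nine right-context characters under the default
maximum pattern length of six yield exactly 15 candidates), then mines a
small synthetic corpus in which anchor-equal contexts were planted and
prints the patterns that survive the 0.8-confidence threshold and the
substring reduction.
"""

from tnorm import GenConfig, generate
from tnorm.pattern_miner import (
    MinerConfig,
    PatternPurpose,
    enumerate_candidates,
    learn,
    substitute_tags,
)

sentence = (
    '遂于<TIMEX3 tid="t9" Type="DATE" Value="2014-09-22" anchorTimeID="t3">'
    "22/9</TIMEX3>行右乳癌改良根治术"
)
templated = substitute_tags(sentence)
print("templated sentence:", templated)
candidates = enumerate_candidates(templated, MinerConfig())
print(f"{len(candidates)} candidate templates, e.g. {candidates[1]!r}")

docs = generate(GenConfig(n_docs=30, seed=0, typo_rate=0.0, planted_pattern_rate=0.5))
patterns = learn(docs, MinerConfig(), PatternPurpose.NORM_ANCHOR_EQUALS)
print(f"\n{len(patterns)} patterns kept at confidence >= 0.8:")
for p in patterns:
    print(f"  {p.template!r}  support={p.support}  confidence={p.confidence:.2f}")

# A TE matching one of these contexts takes its reference time's value
# verbatim instead of the computed offset — the 术后…返院 correction.
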