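"""Six-step context-pattern learning: substitution, enumeration, scoring,
threshold filtering and substring reduction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnorm import GenConfig, generate, read_timeml
from tnorm.pattern_miner import (
    PLACEHOLDER,
    ContextPattern,
    MinerConfig,
    PatternPurpose,
    enumerate_candidates,
    filter_patterns,
    learn,
    load_patterns,
    save_patterns,
    score_patterns,
    substitute_tags,
)

NORM = PatternPurpose.NORM_ANCHOR_EQUALS


def test_substitute_tags(worked_sentence):
    assert substitute_tags(worked_sentence) == "遂于<TIMEX3>行右乳癌改良根治术"


def test_substitute_tags_bare():
    assert substitute_tags('<TIMEX3 tid="t1" Type="DATE" Value="2014">x</TIMEX3>') == PLACEHOLDER


def test_substitute_tags_two_annotations():
    s = ('于<TIMEX3 tid="t1" Type="DATE" Value="2014">a</TIMEX3>至'
         '<TIMEX3 tid="t2" Type="DATE" Value="2015">b</TIMEX3>间')
    assert substitute_tags(s) == f"于{PLACEHOLDER}至{PLACEHOLDER}间"


def test_substitute_tags_requires_annotation():
    with pytest.raises(ValueError):
        substitute_tags("无标注句子")


def test_enumerate_fifteen_candidates(worked_sentence):
    """Two left-context and nine right-context characters under maximum
    pattern length six give 6+5+4 = 15 candidates."""
    cands = enumerate_candidates(substitute_tags(worked_sentence), MinerConfig())
    assert len(cands) == 15
    assert PLACEHOLDER in cands
    assert "遂于<TIMEX3>行右乳" in cands  # length-6 template


def test_enumerate_bare_placeholder():
    assert enumerate_candidates(PLACEHOLDER, MinerConfig()) == [PLACEHOLDER]


def test_enumerate_small_example():
    cands = enumerate_candidates("于<TIMEX3>行", MinerConfig())
    assert sorted(cands) == sorted(
        [PLACEHOLDER, f"于{PLACEHOLDER}", f"{PLACEHOLDER}行", f"于{PLACEHOLDER}行"]
    )


def _brute_force(templated: str, max_len: int) -> set:
    s = templated.replace(PLACEHOLDER, "@")
    out = set()
    for i in range(len(s)):
        for j in range(i + 1, min(len(s), i + max_len) + 1):
            sub = s[i:j]
            if sub.count("@") == 1:
                out.add(sub.replace("@", PLACEHOLDER))
    return out


@settings(max_examples=150, derandomize=True)
@given(
    st.text(alphabet="于行术后前abc", max_size=28),
    st.integers(0, 28),
    st.integers(1, 8),
)
def test_enumeration_matches_brute_force(text, pos, max_len):
    pos = min(pos, len(text))
    templated = text[:pos] + PLACEHOLDER + text[pos:]
    cfg = MinerConfig(max_pattern_len=max_len)
    assert set(enumerate_candidates(templated, cfg)) == _brute_force(templated, max_len)


# --------------------------------------------------------------------------
# scoring on a hand-countable fixture

_FIXTURE = [
    # t2 anchor-equal (value == reference value), in context 术后…返
    '入院日期:<TIMEX3 tid="t1" Type="DATE" Value="2014-01-05">2014年1月5日</TIMEX3>\n'
    '术后<TIMEX3 tid="t2" Type="DATE" Value="2014-01-05" anchorTimeID="t1">3月余</TIMEX3>返院。',
    # same context but the value differs from the reference: not anchor-equal
    '入院日期:<TIMEX3 tid="t1" Type="DATE" Value="2014-02-01">2014年2月1日</TIMEX3>\n'
    '术后<TIMEX3 tid="t2" Type="DATE" Value="2014-05-01" anchorTimeID="t1">3月余</TIMEX3>返院。',
    # no relevant context at all
    '化疗于<TIMEX3 tid="t1" Type="DATE" Value="2014-03-08">2014年3月8日</TIMEX3>进行。',
]


def test_score_patterns_hand_counted():
    docs = [read_timeml(s, doc_id=f"f{i}") for i, s in enumerate(_FIXTURE)]
    cands = [f"术后{PLACEHOLDER}返", PLACEHOLDER, f"术后{PLACEHOLDER}", f"无{PLACEHOLDER}"]
    scored = {p.template: p for p in score_patterns(cands, docs, NORM)}
    # 术后_返 matches the two 3月余 sites; only the first is anchor-equal
    assert scored[f"术后{PLACEHOLDER}返"].support == 2
    assert scored[f"术后{PLACEHOLDER}返"].confidence == pytest.approx(0.5)
    # the bare placeholder matches all five gold TEs, one anchor-equal
    assert scored[PLACEHOLDER].support == 5
    assert scored[PLACEHOLDER].confidence == pytest.approx(0.2)
    assert scored[f"术后{PLACEHOLDER}"].support == 2
    # unseen context never fires
    assert scored[f"无{PLACEHOLDER}"].support == 0


def test_score_patterns_ratio_convention():
    """support 5 with 4 correct sites gives confidence 0.8 exactly."""
    docs = []
    for i in range(5):
        equal = i < 4
        v_ref = "2014-01-05"
        v = v_ref if equal else "2014-04-05"
        docs.append(read_timeml(
            f'日期:<TIMEX3 tid="t1" Type="DATE" Value="{v_ref}">2014年1月5日</TIMEX3>\n'
            f'术后<TIMEX3 tid="t2" Type="DATE" Value="{v}" anchorTimeID="t1">3月余</TIMEX3>返院。',
            doc_id=f"d{i}",
        ))
    (p,) = score_patterns([f"术后{PLACEHOLDER}返"], docs, NORM)
    assert p.support == 5 and p.confidence == pytest.approx(0.8)


# --------------------------------------------------------------------------
# threshold semantics and substring reduction


def _pat(template, conf, support=10):
    return ContextPattern(template=template, purpose=NORM, support=support, confidence=conf)


def test_threshold_is_inclusive():
    cfg = MinerConfig(threshold=0.8)
    kept = filter_patterns([_pat(f"予{PLACEHOLDER}", 0.80)], cfg)
    assert len(kept) == 1
    assert filter_patterns([_pat(f"予{PLACEHOLDER}", 0.79)], cfg) == []


def test_zero_support_dropped():
    assert filter_patterns([_pat(f"予{PLACEHOLDER}", 0.0, support=0)], MinerConfig()) == []


def test_substring_reduction():
    """The shorter template wins unless the longer is strictly more
    confident."""
    pats = [
        _pat(f"予{PLACEHOLDER}", 1.0),
        _pat(f"可予{PLACEHOLDER}", 0.9),
        _pat(f"{PLACEHOLDER}办", 1.0),
    ]
    kept = {p.template for p in filter_patterns(pats, MinerConfig())}
    assert kept == {f"予{PLACEHOLDER}", f"{PLACEHOLDER}办"}


def test_more_confident_superstring_survives():
    pats = [_pat(f"予{PLACEHOLDER}", 0.85), _pat(f"可予{PLACEHOLDER}", 0.95)]
    kept = {p.template for p in filter_patterns(pats, MinerConfig())}
    assert kept == {f"予{PLACEHOLDER}", f"可予{PLACEHOLDER}"}


def test_filter_output_is_substring_minimal(planted_docs):
    cfg = MinerConfig()
    kept = learn(planted_docs, cfg, NORM)
    keys = {p.key(): p.confidence for p in kept}
    for p in kept:
        for qk, qconf in keys.items():
            if qk != p.key() and qk in p.key():
                assert qconf < p.confidence


# --------------------------------------------------------------------------
# learning end to end


def test_learn_worked_example_unfiltered(worked_sentence):
    scored = learn([worked_sentence], MinerConfig(threshold=0.0),
                   PatternPurpose.EXTRACTION, apply_filter=False)
    assert len(scored) == 15
    assert all(p.support >= 1 for p in scored)


def test_learn_empty_corpus():
    assert learn([], MinerConfig(), NORM) == []


def test_planted_pattern_recovery():
    """A context planted around anchor-equal TEs is recovered (as itself or
    a fully confident substring of it) for nearly every seed."""
    hits = 0
    seeds = range(20)
    for seed in seeds:
        docs = generate(GenConfig(n_docs=12, seed=seed, typo_rate=0.0,
                                  planted_pattern_rate=1.0))
        kept = learn(docs, MinerConfig(), NORM)
        planted_key = ContextPattern(template=f"术后{PLACEHOLDER}返", purpose=NORM).key()
        if any(p.key() in planted_key and p.confidence >= 0.8 for p in kept):
            hits += 1
    assert hits / len(seeds) >= 0.95


def test_support_additive_over_concatenation(planted_docs):
    cand = [f"术后{PLACEHOLDER}返"]
    half1 = score_patterns(cand, planted_docs[:15], NORM)[0].support
    half2 = score_patterns(cand, planted_docs[15:], NORM)[0].support
    full = score_patterns(cand, planted_docs, NORM)[0].support
    assert full == half1 + half2


def test_pattern_tsv_round_trip(tmp_path, planted_docs):
    pats = learn(planted_docs, MinerConfig(), NORM)
    path = tmp_path / "patterns.tsv"
    save_patterns(pats, path)
    assert load_patterns(path) == pats
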