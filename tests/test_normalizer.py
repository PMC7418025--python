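"""Value computation: direct parses, calendar offsets, durations, day sets,
pattern corrections and the assembled pipeline."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnorm import (
    CalendarDate,
    RelativeSpec,
    TimexType,
    annotate,
    apply_correction,
    apply_offset,
    format_iso,
    normalize_direct,
    normalize_duration,
    normalize_partial_date,
    normalize_set,
    parse_iso,
    parse_relative,
    read_timeml,
)
from tnorm.normalizer import NormalizationError
from tnorm.pattern_miner import ContextPattern, PatternPurpose


@pytest.mark.parametrize(
    "surface,expected",
    [
        ("2014年6月3日", "2014-06-03"),
        ("2014年6月", "2014-06"),
        ("2014年", "2014"),
        ("2014-10-13", "2014-10-13"),
        ("2014/10/11 7:48:16", "2014-10-11T07:48:16"),
        ("2014年6月3日上午7点20分4秒", "2014-06-03T07:20:04"),
        ("下午3点10分", "T15:10:00"),
    ],
)
def test_normalize_direct(surface, expected):
    assert format_iso(normalize_direct(surface, TimexType.DATE)) == expected


def test_normalize_direct_rejects_relative():
    with pytest.raises(NormalizationError):
        normalize_direct("6天前", TimexType.DATE)


@pytest.mark.parametrize(
    "surface,magnitude,unit,direction,approx",
    [
        ("6天前", 6, "DAY", "BEFORE", False),
        ("72小时后", 72, "HOUR", "AFTER", False),
        ("1 周前", 1, "WEEK", "BEFORE", False),
        ("3月余", 3, "MONTH", "AFTER", True),  # elapsed-time reading
        ("两个月前", 2, "MONTH", "BEFORE", False),
        ("目前", 0, "DAY", "SAME", False),
    ],
)
def test_parse_relative(surface, magnitude, unit, direction, approx):
    spec = parse_relative(surface)
    assert (spec.magnitude, spec.unit, spec.direction, spec.approx) == (
        magnitude, unit, direction, approx,
    )


def test_parse_relative_rejects_nonrelative():
    with pytest.raises(NormalizationError):
        parse_relative("右乳腺癌")


@pytest.mark.parametrize(
    "ref,surface,expected",
    [
        ("2014-10-23", "6天前", "2014-10-17"),
        ("2014-08-09", "1 周前", "2014-08-02"),
        ("2014-10-20", "72小时后", "2014-10-23"),
        ("2014-10-17", "目前", "2014-10-17"),
    ],
)
def test_apply_offset_examples(ref, surface, expected):
    out = apply_offset(parse_iso(ref), parse_relative(surface))
    assert format_iso(out) == expected


def test_month_offset_clamps_day():
    out = apply_offset(CalendarDate(2014, 3, 31), RelativeSpec(1, "MONTH", "BEFORE"))
    assert format_iso(out) == "2014-02-28"


def test_month_offsets_match_pandas_calendar():
    """Independent cross-check of month arithmetic against pandas."""
    import pandas as pd

    for iso, months in [("2014-03-31", 1), ("2014-12-15", 3), ("2016-02-29", 12),
                        ("2014-07-31", 2), ("2015-01-31", 11)]:
        ours = apply_offset(parse_iso(iso), RelativeSpec(months, "MONTH", "BEFORE"))
        theirs = pd.Timestamp(iso) - pd.DateOffset(months=months)
        assert format_iso(ours) == theirs.date().isoformat()


def test_offset_requires_precision():
    with pytest.raises(NormalizationError):
        apply_offset(CalendarDate(2014), RelativeSpec(3, "MONTH", "BEFORE"))
    with pytest.raises(NormalizationError):
        apply_offset(CalendarDate(2014, 6), RelativeSpec(2, "DAY", "AFTER"))


@settings(max_examples=150, derandomize=True)
@given(
    st.dates(datetime.date(1990, 1, 1), datetime.date(2050, 12, 31)),
    st.integers(1, 60),
    st.sampled_from(["DAY", "WEEK"]),
)
def test_offset_involution_on_uniform_units(date, n, unit):
    """BEFORE then AFTER by the same amount returns to the start for units
    of fixed length."""
    ref = CalendarDate(date.year, date.month, date.day)
    back = apply_offset(ref, RelativeSpec(n, unit, "BEFORE"))
    forth = apply_offset(back, RelativeSpec(n, unit, "AFTER"))
    assert forth == ref


@settings(max_examples=150, derandomize=True)
@given(
    st.dates(datetime.date(1990, 1, 1), datetime.date(2050, 12, 31)),
    st.integers(1, 60),
    st.sampled_from(["DAY", "WEEK"]),
)
def test_day_offsets_match_timedelta_oracle(date, n, unit):
    days = n * (7 if unit == "WEEK" else 1)
    expected = date - datetime.timedelta(days=days)
    out = apply_offset(CalendarDate(date.year, date.month, date.day),
                       RelativeSpec(n, unit, "BEFORE"))
    assert format_iso(out) == expected.isoformat()


@pytest.mark.parametrize(
    "surface,expected",
    [
        ("两年五个月", "P2Y5M"),
        ("1年余", "P1Y"),
        ("一个月", "P1M"),
        ("三周", "P3W"),
        ("72小时", "PT72H"),
    ],
)
def test_normalize_duration(surface, expected):
    assert format_iso(normalize_duration(surface)) == expected


def test_normalize_duration_rejects_plain_text():
    with pytest.raises(NormalizationError):
        normalize_duration("良好")


@pytest.mark.parametrize(
    "surface,ref,expected",
    [
        ("第1天", "2014-09-22", "[2014-09-22]"),
        ("第7、10、14天", "2014-09-01", "[2014-09-07,2014-09-10,2014-09-14]"),
        ("第2、3天", "2014-12-31", "[2015-01-01,2015-01-02]"),  # year boundary
    ],
)
def test_normalize_set(surface, ref, expected):
    assert format_iso(normalize_set(surface, parse_iso(ref))) == expected


def test_normalize_set_requires_day_precision():
    with pytest.raises(NormalizationError):
        normalize_set("第2天", CalendarDate(2014, 12))


def test_partial_dates_complete_from_reference():
    assert format_iso(normalize_partial_date("22/9", parse_iso("2014-10-11"))) == "2014-09-22"
    assert format_iso(normalize_partial_date("2月", parse_iso("2014-10-23"))) == "2014-02"


# --------------------------------------------------------------------------
# corrections


def _doc_with_anchor(text):
    return read_timeml(text)


def test_correction_overrides_with_reference_value():
    doc = read_timeml(
        '手术于<TIMEX3 tid="t1" Type="DATE" Value="2014-06-20">2014-06-20</TIMEX3>进行。'
        '术后<TIMEX3 tid="t2" Type="DATE" Value="" anchorTimeID="t1">3月余</TIMEX3>,返院行化疗'
    )
    pat = ContextPattern(template="术后<TIMEX3>", purpose=PatternPurpose.NORM_ANCHOR_EQUALS,
                         support=9, confidence=1.0)
    override = apply_correction(doc, doc.by_tid("t2"), [pat],
                                parse_iso("2014-06-20"))
    assert format_iso(override) == "2014-06-20"


def test_no_matching_pattern_keeps_offset_value():
    doc = read_timeml(
        '入院于<TIMEX3 tid="t1" Type="DATE" Value="2014-10-23">2014-10-23</TIMEX3>,'
        '<TIMEX3 tid="t2" Type="DATE" Value="" anchorTimeID="t1">6天前</TIMEX3>发病'
    )
    pat = ContextPattern(template="术后<TIMEX3>", purpose=PatternPurpose.NORM_ANCHOR_EQUALS,
                         support=9, confidence=1.0)
    assert apply_correction(doc, doc.by_tid("t2"), [pat], parse_iso("2014-10-23")) is None


def test_documented_misfire_reproduced():
    """An over-general learned pattern can wrongly equate a relative TE with
    its reference: 6天前 followed by 于我院 matches <TIMEX3>于我 and the
    override replaces the correct offset value with the reference value."""
    doc = read_timeml(
        '入院于<TIMEX3 tid="t1" Type="DATE" Value="2014-10-23">2014-10-23</TIMEX3>。'
        '<TIMEX3 tid="t2" Type="DATE" Value="" anchorTimeID="t1">6天前</TIMEX3>'
        "于我院行双乳B超"
    )
    pat = ContextPattern(template="<TIMEX3>于我", purpose=PatternPurpose.NORM_ANCHOR_EQUALS,
                         support=4, confidence=0.9)
    override = apply_correction(doc, doc.by_tid("t2"), [pat], parse_iso("2014-10-23"))
    assert format_iso(override) == "2014-10-23"  # wrong but faithful
    correct = apply_offset(parse_iso("2014-10-23"), parse_relative("6天前"))
    assert format_iso(correct) == "2014-10-17"


# --------------------------------------------------------------------------
# assembled pipeline


def test_annotate_single_date():
    doc = annotate("2014-10-13")
    assert len(doc.timexes) == 1
    tx = doc.timexes[0]
    assert (tx.tid, tx.ttype, tx.value) == ("t1", TimexType.DATE, "2014-10-13")


def test_annotate_no_timexes():
    doc = annotate("无时间信息的文本。")
    assert doc.timexes == [] and doc.text == "无时间信息的文本。"


def test_annotate_failure_leaves_value_empty():
    # a relative TE with no possible reference: emitted, value empty
    doc = annotate("患者6天前发病。")
    assert len(doc.timexes) == 1
    assert doc.timexes[0].value == ""


def test_annotate_is_idempotent_on_plain_text(clean_docs):
    from tnorm import write_timeml

    doc = clean_docs[0]
    first = annotate(doc.text, doc_id=doc.doc_id)
    second = annotate(first.text, doc_id=doc.doc_id)
    assert write_timeml(first) == write_timeml(second)
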