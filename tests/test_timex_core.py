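"""ISO 8601 codec and inline TIMEX3 markup round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnorm import (
    CalendarDate,
    ClockTime,
    DateSet,
    Document,
    Duration,
    Timex3,
    TimexType,
    format_iso,
    parse_iso,
    read_timeml,
    write_timeml,
)
from tnorm.timex_core import (
    EventKind,
    IsoParseError,
    TimeMLParseError,
    parse_header_events,
)


@pytest.mark.parametrize(
    "value,expected",
    [
        ("P2Y5M", Duration(years=2, months=5)),
        ("2014", CalendarDate(2014)),
        ("2014-06", CalendarDate(2014, 6)),
        ("2014-06-03", CalendarDate(2014, 6, 3)),
        ("2014-6-3", CalendarDate(2014, 6, 3)),  # lenient unpadded
        ("2014-2", CalendarDate(2014, 2)),
        ("2014-06-03T07:20:04", ClockTime(CalendarDate(2014, 6, 3), 7, 20, 4)),
        ("T07:20:04", ClockTime(None, 7, 20, 4)),
        ("P1M", Duration(months=1)),
        ("P3W", Duration(weeks=3)),
        ("PT3H", Duration(hours=3)),
        ("[2014-09-07,2014-09-10]", DateSet((CalendarDate(2014, 9, 7), CalendarDate(2014, 9, 10)))),
    ],
)
def test_parse_iso(value, expected):
    assert parse_iso(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [
        (CalendarDate(2014, 6, 3), "2014-06-03"),
        (Duration(months=1), "P1M"),
        (CalendarDate(2014), "2014"),
        (Duration(years=2, months=5), "P2Y5M"),
        (Duration(weeks=3), "P3W"),
        # mixed weeks are converted to days (ISO forbids mixing W)
        (Duration(weeks=1, days=2), "P9D"),
        (ClockTime(CalendarDate(2014, 10, 11), 7, 48, 16), "2014-10-11T07:48:16"),
    ],
)
def test_format_iso(value, expected):
    assert format_iso(value) == expected


@pytest.mark.parametrize(
    "bad", ["", "P", "PT", "2014-13", "2014-02-30", "20x4", "[2014-01-01", "[P1M]"]
)
def test_parse_iso_rejects_malformed(bad):
    with pytest.raises(IsoParseError):
        parse_iso(bad)


_dates = st.builds(
    CalendarDate,
    year=st.integers(1900, 2100),
    month=st.integers(1, 12),
    day=st.integers(1, 28),
)
_partial_dates = st.one_of(
    st.builds(CalendarDate, year=st.integers(1900, 2100)),
    st.builds(CalendarDate, year=st.integers(1900, 2100), month=st.integers(1, 12)),
    _dates,
)
_durations = (
    st.tuples(st.integers(0, 5), st.integers(0, 11), st.integers(0, 30),
              st.integers(0, 23))
    .filter(any)
    .map(lambda t: Duration(years=t[0], months=t[1], days=t[2], hours=t[3]))
)
_clock = st.builds(
    ClockTime,
    date=st.one_of(st.none(), _dates),
    hour=st.integers(0, 23),
    minute=st.integers(0, 59),
    second=st.integers(0, 59),
)
_iso_values = st.one_of(
    _partial_dates,
    _durations,
    _clock,
    st.builds(DateSet, st.lists(_dates, min_size=1, max_size=4).map(tuple)),
)


@settings(max_examples=200, derandomize=True)
@given(_iso_values)
def test_iso_round_trip(v):
    assert parse_iso(format_iso(v)) == v


def test_read_timeml_example():
    doc = read_timeml(
        '<TIMEX3 tid="t1" Type="TIME" Value="2014-10-11T07:48:16">2014/10/11 7:48:16</TIMEX3>'
    )
    assert len(doc.timexes) == 1
    tx = doc.timexes[0]
    assert tx.ttype == TimexType.TIME
    assert tx.surface == "2014/10/11 7:48:16"
    assert doc.text == "2014/10/11 7:48:16"
    assert tx.span == (0, 18)


def test_read_timeml_anchor():
    doc = read_timeml(
        '入院于<TIMEX3 tid="t2" Type="DATE" Value="2014-08-09">2014年8月9日</TIMEX3>,'
        '<TIMEX3 tid="t7" Type="DATE" Value="2014-08-02" anchorTimeID="t2">1 周前</TIMEX3>发病'
    )
    assert doc.timexes[1].anchor_tid == "t2"
    assert doc.text.startswith("入院于2014年8月9日")


def test_read_timeml_no_markup():
    doc = read_timeml("no markup at all")
    assert doc.timexes == [] and doc.text == "no markup at all"


@pytest.mark.parametrize(
    "markup",
    [
        '<TIMEX3 tid="t1" Type="DATE" Value="2014">x',  # unclosed
        '<TIMEX3 tid="t1" Type="WHEN" Value="2014">x</TIMEX3>',  # unknown type
        '<TIMEX3 tid="t1" Type="DATE" Value="2014">x</TIMEX3>'
        '<TIMEX3 tid="t1" Type="DATE" Value="2015">y</TIMEX3>',  # duplicate tid
        '<TIMEX3 Type="DATE" Value="2014">x</TIMEX3>',  # missing tid
        '<TIMEX3 tid="t1" Type="DATE" Value="2014" anchorTimeID="t9">x</TIMEX3>',
    ],
)
def test_read_timeml_errors(markup):
    with pytest.raises(TimeMLParseError) as exc:
        read_timeml(markup)
    assert exc.value.offset >= 0


def test_dangling_anchor_tolerated_when_lenient(worked_sentence):
    doc = read_timeml(worked_sentence, strict=False)
    assert doc.timexes[0].anchor_tid == "t3"


def test_write_timeml_duration_example():
    doc = read_timeml('病程<TIMEX3 tid="t4" Type="DURATION" Value="P1Y">1年余</TIMEX3>')
    out = write_timeml(doc)
    assert '<TIMEX3 tid="t4" Type="DURATION" Value="P1Y">1年余</TIMEX3>' in out


def test_write_timeml_empty_document():
    doc = Document(doc_id="d", text="纯文本，无标注。")
    assert write_timeml(doc) == doc.text


def test_timeml_round_trip_on_generated_documents(clean_docs):
    for doc in clean_docs[:10]:
        recovered = read_timeml(write_timeml(doc), doc_id=doc.doc_id)
        assert recovered.text == doc.text
        assert [
            (t.tid, t.ttype, t.value, t.span, t.surface, t.anchor_tid)
            for t in recovered.timexes
        ] == [
            (t.tid, t.ttype, t.value, t.span, t.surface, t.anchor_tid)
            for t in doc.timexes
        ]


def test_document_validation_rejects_bad_span():
    doc = Document(
        doc_id="d",
        text="2014年",
        timexes=[Timex3(tid="t1", ttype=TimexType.DATE, value="2014",
                        span=(0, 5), surface="2014年X")],
    )
    with pytest.raises(ValueError):
        doc.validate()


def test_header_events():
    events = parse_header_events("入院日期:2014-10-11\n出院日期:2014年10月23日\n")
    assert format_iso(events[EventKind.ADMISSION]) == "2014-10-11"
    assert format_iso(events[EventKind.DISCHARGE]) == "2014-10-23"
    # the documented corruption leaves the discharge time unknown
    assert EventKind.DISCHARGE not in parse_header_events("出院日期:出院日期\n")
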