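"""Domain types, ISO 8601 value codec, and inline TIMEX3 (TimeML) I/O.

A temporal expression (TE) in a clinical narrative is annotated inline as

    <TIMEX3 tid="t7" Type="DATE" Value="2014-08-02" anchorTimeID="t2">1 周前</TIMEX3>

with the four TimeML attributes: ``tid`` (document-unique id ``t1, t2, ...``),
``Type`` (DATE / TIME / DURATION / SET), ``Value`` (the normalized ISO 8601
string) and the optional ``anchorTimeID`` naming the reference TE the value was
computed from.  Values are structured here as :class:`IsoValue` variants:
calendar dates at year/month/day precision, clock times, durations
(``PnYnMnDTnHnMnS``), and date sets (a bracketed list of dates, used for
enumerations like 第7、10、14天).
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Union

__all__ = [
    "TimexType",
    "EventKind",
    "CalendarDate",
    "ClockTime",
    "Duration",
    "DateSet",
    "IsoValue",
    "Timex3",
    "Document",
    "IsoParseError",
    "TimeMLParseError",
    "parse_iso",
    "format_iso",
    "read_timeml",
    "write_timeml",
    "parse_header_events",
]


class TimexType(str, Enum):
    DATE = "DATE"
    TIME = "TIME"
    DURATION = "DURATION"
    SET = "SET"


class EventKind(str, Enum):
    """Critical clinical events whose occurrence time can anchor nearby TEs."""

    ADMISSION = "ADMISSION"
    DISCHARGE = "DISCHARGE"
    SURGERY = "SURGERY"
    CHEMOTHERAPY = "CHEMOTHERAPY"
    RETURN = "RETURN"


class IsoParseError(ValueError):
    """Raised when an ISO 8601 value string cannot be parsed."""

    def __init__(self, message: str, token: str = ""):
        super().__init__(message)
        self.token = token


class TimeMLParseError(ValueError):
    """Raised on malformed inline TIMEX3 markup; carries the character offset."""

    def __init__(self, message: str, offset: int = -1):
        super().__init__(f"{message} (at offset {offset})" if offset >= 0 else message)
        self.offset = offset


# --------------------------------------------------------------------------
# ISO values


@dataclass(frozen=True, order=True)
class CalendarDate:
    """A calendar date at year, month, or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.month is None and self.day is not None:
            raise ValueError("day without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            ndays = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= ndays:
                raise ValueError(f"day out of range: {self.year}-{self.month}-{self.day}")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"


@dataclass(frozen=True)
class ClockTime:
    """A clock time, optionally attached to a (day-precise) calendar date."""

    date: Optional[CalendarDate]
    hour: int
    minute: int
    second: int

    def __post_init__(self) -> None:
        if self.date is not None and self.date.precision != "day":
            raise ValueError("clock time requires a day-precise date")
        if not (0 <= self.hour <= 23 and 0 <= self.minute <= 59 and 0 <= self.second <= 59):
            raise ValueError(f"clock fields out of range: {self.hour}:{self.minute}:{self.second}")


@dataclass(frozen=True)
class Duration:
    """An ISO 8601 duration; components are non-negative, at least one nonzero.

    Weeks are kept only when pure (``P3W``); the formatter converts weeks mixed
    with other components to days, since ISO 8601 forbids combining the week
    designator with others.
    """

    years: int = 0
    months: int = 0
    weeks: int = 0
    days: int = 0
    hours: int = 0
    minutes: int = 0
    seconds: int = 0

    def __post_init__(self) -> None:
        comps = (self.years, self.months, self.weeks, self.days,
                 self.hours, self.minutes, self.seconds)
        if any(c < 0 for c in comps):
            raise ValueError("negative duration component")
        if not any(comps):
            raise ValueError("duration must have at least one nonzero component")


@dataclass(frozen=True)
class DateSet:
    """A non-empty ordered set of calendar dates (e.g. follow-up days 7, 10, 14)."""

    dates: tuple[CalendarDate, ...]

    def __post_init__(self) -> None:
        if not self.dates:
            raise ValueError("empty date set")


IsoValue = Union[CalendarDate, ClockTime, Duration, DateSet]


_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")
_CLOCK_RE = re.compile(
    r"^(?:(\d{4})-(\d{1,2})-(\d{1,2}))?T(\d{1,2}):(\d{1,2}):(\d{1,2})$"
)
_DURATION_RE = re.compile(
    r"^P(?:(\d+)Y)?(?:(\d+)M)?(?:(\d+)W)?(?:(\d+)D)?"
    r"(?:T(?:(\d+)H)?(?:(\d+)M)?(?:(\d+)S)?)?$"
)


def parse_iso(value: str) -> IsoValue:
    """Parse an ISO 8601 value string into a structured :class:`IsoValue`.

    Accepts zero-padded and, leniently, unpadded months/days ("2014-2" is read
    as February 2014); the formatter always pads.  Precision is preserved:
    "2014" stays a year-precision date.
    """
    if not value:
        raise IsoParseError("empty ISO value", value)
    if value.startswith("["):
        if not value.endswith("]"):
            raise IsoParseError("unterminated date set", value)
        inner = value[1:-1]
        parts = [p.strip() for p in inner.split(",")] if inner.strip() else []
        if not parts:
            raise IsoParseError("empty date set", value)
        dates = []
        for p in parts:
            d = parse_iso(p)
            if not isinstance(d, CalendarDate):
                raise IsoParseError("date set member is not a calendar date", p)
            dates.append(d)
        return DateSet(tuple(dates))
    if value.startswith("P"):
        m = _DURATION_RE.match(value)
        if m is None or value in ("P", "PT"):
            raise IsoParseError("malformed duration", value)
        y, mo, w, d, h, mi, s = (int(g) if g else 0 for g in m.groups())
        try:
            return Duration(y, mo, w, d, h, mi, s)
        except ValueError as e:
            raise IsoParseError(str(e), value) from e
    if "T" in value:
        m = _CLOCK_RE.match(value)
        if m is None:
            raise IsoParseError("malformed clock time", value)
        yy, mo, dd, h, mi, s = m.groups()
        date = None
        if yy is not None:
            try:
                date = CalendarDate(int(yy), int(mo), int(dd))
            except ValueError as e:
                raise IsoParseError(str(e), value) from e
        try:
            return ClockTime(date, int(h), int(mi), int(s))
        except ValueError as e:
            raise IsoParseError(str(e), value) from e
    m = _DATE_RE.match(value)
    if m is None:
        raise IsoParseError("malformed calendar date", value)
    yy, mo, dd = m.groups()
    try:
        return CalendarDate(int(yy), int(mo) if mo else None, int(dd) if dd else None)
    except ValueError as e:
        raise IsoParseError(str(e), value) from e


def _fmt_date(d: CalendarDate) -> str:
    if d.day is not None:
        return f"{d.year:04d}-{d.month:02d}-{d.day:02d}"
    if d.month is not None:
        return f"{d.year:04d}-{d.month:02d}"
    return f"{d.year:04d}"


def format_iso(v: IsoValue) -> str:
    """Serialize an :class:`IsoValue` canonically (zero-padded, zero components
    of durations omitted).  ``parse_iso(format_iso(v)) == v``."""
    if isinstance(v, CalendarDate):
        return _fmt_date(v)
    if isinstance(v, ClockTime):
        prefix = _fmt_date(v.date) if v.date is not None else ""
        return f"{prefix}T{v.hour:02d}:{v.minute:02d}:{v.second:02d}"
    if isinstance(v, Duration):
        weeks, days = v.weeks, v.days
        others = (v.years, v.months, v.days, v.hours, v.minutes, v.seconds)
        if weeks and any(others):
            days += 7 * weeks  # ISO 8601: W cannot mix with other designators
            weeks = 0
        out = "P"
        for n, tag in ((v.years, "Y"), (v.months, "M"), (weeks, "W"), (days, "D")):
            if n:
                out += f"{n}{tag}"
        if v.hours or v.minutes or v.seconds:
            out += "T"
            for n, tag in ((v.hours, "H"), (v.minutes, "M"), (v.seconds, "S")):
                if n:
                    out += f"{n}{tag}"
        return out
    if isinstance(v, DateSet):
        return "[" + ",".join(_fmt_date(d) for d in v.dates) + "]"
    raise TypeError(f"not an IsoValue: {v!r}")


# --------------------------------------------------------------------------
# Documents and TIMEX3 markup


_TID_RE = re.compile(r"^t[1-9][0-9]*$")


@dataclass
class Timex3:
    """One annotated temporal mention."""

    tid: str
    ttype: TimexType
    value: str
    span: tuple[int, int]
    surface: str
    anchor_tid: Optional[str] = None

    def __post_init__(self) -> None:
        if not _TID_RE.match(self.tid):
            raise ValueError(f"bad tid: {self.tid!r}")
        self.ttype = TimexType(self.ttype)

    def iso(self) -> Optional[IsoValue]:
        """Structured value, or None when the value is empty (unnormalizable TE)."""
        return parse_iso(self.value) if self.value else None


@dataclass
class Document:
    """A clinical narrative with its temporal annotations.

    ``header_events`` maps critical-event kinds to occurrence times taken from
    structured header lines such as ``入院日期:2014-10-11``.
    """

    doc_id: str
    text: str
    timexes: list[Timex3] = field(default_factory=list)
    header_events: dict[EventKind, Optional[IsoValue]] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        prev_end = 0
        for tx in self.timexes:
            b, e = tx.span
            if b < prev_end:
                raise ValueError(f"overlapping or unsorted span for {tx.tid}")
            prev_end = e
            if self.text[b:e] != tx.surface:
                raise ValueError(f"surface mismatch for {tx.tid}")
            if tx.tid in seen:
                raise ValueError(f"duplicate tid {tx.tid}")
            seen.add(tx.tid)
            if tx.value:
                parse_iso(tx.value)
        for tx in self.timexes:
            if tx.anchor_tid is not None and tx.anchor_tid not in seen:
                raise ValueError(f"{tx.tid} anchors unknown tid {tx.anchor_tid}")

    def by_tid(self, tid: str) -> Timex3:
        for tx in self.timexes:
            if tx.tid == tid:
                return tx
        raise KeyError(tid)


_OPEN_TAG_RE = re.compile(r"<TIMEX3\b([^>]*)>")
_ATTR_RE = re.compile(r'(\w+)\s*=\s*["“”]([^"“”]*)["“”]')
_CLOSE = "</TIMEX3>"

# Structured header lines: 入院日期:2014-10-11 (value may be date or date+clock)
_HEADER_RE = re.compile(
    r"^(入院日期|出院日期|手术日期|化疗日期|返院日期)\s*[:：]\s*"
    r"(\d{4}[-/年]\d{1,2}[-/月]\d{1,2}日?(?:\s*\d{1,2}:\d{1,2}:\d{1,2})?)",
    re.MULTILINE,
)
_HEADER_KIND = {
    "入院日期": EventKind.ADMISSION,
    "出院日期": EventKind.DISCHARGE,
    "手术日期": EventKind.SURGERY,
    "化疗日期": EventKind.CHEMOTHERAPY,
    "返院日期": EventKind.RETURN,
}


def parse_header_events(text: str) -> dict[EventKind, Optional[IsoValue]]:
    """Extract occurrence times from structured header lines of a narrative."""
    out: dict[EventKind, Optional[IsoValue]] = {}
    for m in _HEADER_RE.finditer(text):
        raw = m.group(2)
        datepart = re.match(r"(\d{4})[-/年](\d{1,2})[-/月](\d{1,2})日?", raw)
        assert datepart is not None
        date = CalendarDate(int(datepart.group(1)), int(datepart.group(2)), int(datepart.group(3)))
        clock = re.search(r"(\d{1,2}):(\d{1,2}):(\d{1,2})", raw)
        value: IsoValue = date
        if clock:
            value = ClockTime(date, int(clock.group(1)), int(clock.group(2)), int(clock.group(3)))
        out.setdefault(_HEADER_KIND[m.group(1)], value)
    return out


def read_timeml(annotated: str, doc_id: str = "doc", strict: bool = True) -> Document:
    """Parse inline ``<TIMEX3 ...>...</TIMEX3>`` markup into a :class:`Document`.

    The returned document's ``text`` is the markup-stripped string and every
    span indexes into it (0-based, half-open).  With ``strict=True`` (default)
    an ``anchorTimeID`` must name another TE of the same document; with
    ``strict=False`` dangling anchors are kept as-is, which is needed to load
    isolated example sentences.
    """
    plain: list[str] = []
    timexes: list[Timex3] = []
    seen_tids: set[str] = set()
    pos = 0
    out_len = 0
    while True:
        m = _OPEN_TAG_RE.search(annotated, pos)
        if m is None:
            plain.append(annotated[pos:])
            break
        plain.append(annotated[pos:m.start()])
        out_len += m.start() - pos
        close = annotated.find(_CLOSE, m.end())
        if close < 0:
            raise TimeMLParseError("unclosed <TIMEX3> tag", m.start())
        attrs = dict(_ATTR_RE.findall(m.group(1)))
        for required in ("tid", "Type", "Value"):
            if required not in attrs:
                raise TimeMLParseError(f"missing attribute {required}", m.start())
        tid = attrs["tid"]
        if tid in seen_tids:
            raise TimeMLParseError(f"duplicate tid {tid}", m.start())
        seen_tids.add(tid)
        try:
            ttype = TimexType(attrs["Type"])
        except ValueError:
            raise TimeMLParseError(f"unknown Type {attrs['Type']!r}", m.start()) from None
        value = attrs["Value"]
        if value:
            try:
                parse_iso(value)
            except IsoParseError as e:
                raise TimeMLParseError(f"bad Value {value!r}: {e}", m.start()) from e
        surface = annotated[m.end():close]
        if _OPEN_TAG_RE.search(surface):
            raise TimeMLParseError("nested <TIMEX3> tag", m.end())
        span = (out_len, out_len + len(surface))
        plain.append(surface)
        out_len += len(surface)
        try:
            timexes.append(Timex3(tid=tid, ttype=ttype, value=value, span=span,
                                  surface=surface, anchor_tid=attrs.get("anchorTimeID")))
        except ValueError as e:
            raise TimeMLParseError(str(e), m.start()) from e
        pos = close + len(_CLOSE)
    text = "".join(plain)
    doc = Document(doc_id=doc_id, text=text, timexes=timexes,
                   header_events=parse_header_events(text))
    if strict:
        for tx in timexes:
            if tx.anchor_tid is not None and tx.anchor_tid not in seen_tids:
                raise TimeMLParseError(
                    f"{tx.tid} anchors unknown tid {tx.anchor_tid}", tx.span[0])
    return doc


def write_timeml(doc: Document) -> str:
    """Serialize a document back to inline TIMEX3 markup (round-trips with
    :func:`read_timeml`); attribute order is tid, Type, Value, anchorTimeID."""
    out: list[str] = []
    pos = 0
    for tx in doc.timexes:
        b, e = tx.span
        out.append(doc.text[pos:b])
        attrs = f'tid="{tx.tid}" Type="{tx.ttype.value}" Value="{tx.value}"'
        if tx.anchor_tid is not None:
            attrs += f' anchorTimeID="{tx.anchor_tid}"'
        out.append(f"<TIMEX3 {attrs}>{doc.text[b:e]}</TIMEX3>")
        pos = e
    out.append(doc.text[pos:])
    return "".join(out)


def next_tid(existing: Iterable[str]) -> str:
    """Smallest unused tid following document-order assignment t1, t2, ..."""
    used = {int(t[1:]) for t in existing}
    n = 1
    while n in used:
        n += 1
    return f"t{n}"
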