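"""ISO 8601 normalization of classified temporal expressions.

Direct TEs (absolute dates and clock times) parse straight to values.
Relative TEs (``6天前``, ``72小时后``, deictic ``目前``) are resolved against
a reference time with calendar-aware arithmetic: month offsets clamp the
day-of-month (2014-03-31 minus one month is 2014-02-28), sub-day offsets
against a date-only reference round down to whole days, and the output keeps
the reference's precision.  Durations drop the approximation marker 余/约
(``1年余`` -> ``P1Y``).  Enumerated day sets count the event day as day one:
``第7天`` after chemotherapy on 2014-09-01 is 2014-09-07.

Learned NORM_ANCHOR_EQUALS context patterns then override the computed value
with the reference time's own value where they match — the correction for
contexts like ``术后3月余,返院...`` where the elapsed-time reading is wrong.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from . import anchor_resolver
from .extractor import ExtractionRule, default_rules, extract_spans
from .pattern_miner import ContextPattern, PatternPurpose
from .timex_core import (
    CalendarDate,
    ClockTime,
    DateSet,
    Document,
    Duration,
    IsoValue,
    Timex3,
    TimexType,
    format_iso,
    parse_header_events,
)
from .type_features import LexiconTagger, TaggerPort, build_vector
from .zhnum import parse_number

__all__ = [
    "RelativeSpec",
    "NormalizationError",
    "normalize_direct",
    "normalize_partial_date",
    "parse_relative",
    "apply_offset",
    "normalize_duration",
    "normalize_set",
    "apply_correction",
    "normalize_document",
    "annotate",
]

logger = logging.getLogger("tnorm")

_UNITS = ("YEAR", "MONTH", "WEEK", "DAY", "HOUR", "MINUTE", "SECOND")
_UNIT_MAP = {
    "年": "YEAR", "月": "MONTH", "周": "WEEK", "星期": "WEEK",
    "天": "DAY", "日": "DAY", "小时": "HOUR", "分钟": "MINUTE", "秒": "SECOND",
}


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class RelativeSpec:
    """A parsed relative TE: magnitude, unit, direction, approximation."""

    magnitude: int
    unit: str  # one of _UNITS
    direction: str  # BEFORE | AFTER | SAME
    approx: bool = False

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.direction not in ("BEFORE", "AFTER", "SAME"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction != "SAME" and self.magnitude < 1:
            raise ValueError("magnitude must be >= 1")


# --------------------------------------------------------------------------
# direct (absolute) TEs

_ABS_PATTERNS = (
    re.compile(r"^(\d{4})年(\d{1,2})月(\d{1,2})日$"),
    re.compile(r"^(\d{4})[-/](\d{1,2})[-/](\d{1,2})$"),
)
_ABS_PARTIAL = (
    re.compile(r"^(\d{4})年(\d{1,2})月$"),
    re.compile(r"^(\d{4})-(\d{1,2})$"),
)
_ABS_YEAR = re.compile(r"^(\d{4})年?$")
_CLOCK_TAIL = re.compile(
    r"^(?:(?P<date>.*?)[ \t]?)??(?P<half>上午|下午|凌晨|晚)?"
    r"(?:(?P<h>\d{1,2}):(?P<m>\d{2})(?::(?P<s>\d{2}))?"
    r"|(?P<hc>\d{1,2})[点时](?P<mc>\d{1,2})分(?:(?P<sc>\d{1,2})秒)?)$"
)


def _parse_abs_date(surface: str) -> Optional[CalendarDate]:
    for pat in _ABS_PATTERNS:
        m = pat.match(surface)
        if m:
            return CalendarDate(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    for pat in _ABS_PARTIAL:
        m = pat.match(surface)
        if m:
            return CalendarDate(int(m.group(1)), int(m.group(2)))
    m = _ABS_YEAR.match(surface)
    if m:
        return CalendarDate(int(m.group(1)))
    return None


def normalize_direct(surface: str, ttype: TimexType) -> IsoValue:
    """Normalize an absolute date or clock time (no reference involved).

    Afternoon/evening day-part words shift the hour to the 24-hour clock.
    """
    surface = surface.strip()
    m = _CLOCK_TAIL.match(surface)
    if m and (m.group("h") or m.group("hc")):
        date = None
        if m.group("date"):
            date = _parse_abs_date(m.group("date"))
            if date is None or date.precision != "day":
                raise NormalizationError(f"bad date part in {surface!r}")
        if m.group("h"):
            h, mi, s = int(m.group("h")), int(m.group("m")), int(m.group("s") or 0)
        else:
            h, mi = int(m.group("hc")), int(m.group("mc"))
            s = int(m.group("sc") or 0)
        if m.group("half") in ("下午", "晚") and h < 12:
            h += 12
        return ClockTime(date, h, mi, s)
    date = _parse_abs_date(surface)
    if date is None:
        raise NormalizationError(f"not an absolute date/time: {surface!r}")
    return date


_DM_SLASH = re.compile(r"^(\d{1,2})/(\d{1,2})$")
_MONTH_NAME = re.compile(r"^(\d{1,2})月$")


def normalize_partial_date(surface: str, reference: IsoValue) -> CalendarDate:
    """Complete a partial date from the reference time.

    ``22/9`` (day/month) takes the reference year and becomes a day-precise
    date; a bare month name ``2月`` takes the reference year and stays at
    month precision (same-year reading).
    """
    ref_date = _ref_calendar_date(reference)
    m = _DM_SLASH.match(surface)
    if m:
        day, month = int(m.group(1)), int(m.group(2))
        if month > 12 and day <= 12:  # tolerate M/D order when unambiguous
            day, month = month, day
        return CalendarDate(ref_date.year, month, day)
    m = _MONTH_NAME.match(surface)
    if m:
        return CalendarDate(ref_date.year, int(m.group(1)))
    raise NormalizationError(f"not a partial date: {surface!r}")


# --------------------------------------------------------------------------
# relative TEs

_REL_RE = re.compile(
    r"^(?P<num>\d{1,3}|[一二两三四五六七八九十]{1,3})[ \t]?个?"
    r"(?P<unit>小时|分钟|星期|年|月|周|天|日|秒)[ \t]?"
    r"(?P<approx>[余约多])?(?P<dir>[前后])?$"
)
_DEICTICS = ("目前", "现在", "现", "今", "入院时", "出院时")


def parse_relative(surface: str) -> RelativeSpec:
    """Parse a relative or deictic surface into a :class:`RelativeSpec`.

    前 -> BEFORE, 后 -> AFTER; a bare elapsed-time surface like ``3月余``
    (no direction marker) reads as AFTER the reference event; deictics
    (目前, 现在, ...) are SAME.
    """
    surface = surface.strip()
    if surface in _DEICTICS:
        return RelativeSpec(0, "DAY", "SAME")
    m = _REL_RE.match(surface)
    if m is None:
        raise NormalizationError(f"not a relative TE: {surface!r}")
    magnitude = parse_number(m.group("num"))
    direction = {"前": "BEFORE", "后": "AFTER", None: "AFTER"}[m.group("dir")]
    return RelativeSpec(
        magnitude=magnitude,
        unit=_UNIT_MAP[m.group("unit")],
        direction=direction,
        approx=m.group("approx") is not None,
    )


def _ref_calendar_date(reference: IsoValue) -> CalendarDate:
    if isinstance(reference, CalendarDate):
        return reference
    if isinstance(reference, ClockTime) and reference.date is not None:
        return reference.date
    raise NormalizationError(f"reference is not date-bearing: {reference!r}")


def _shift_months(date: CalendarDate, months: int) -> CalendarDate:
    total = date.year * 12 + (date.month - 1) + months
    year, month = divmod(total, 12)
    month += 1
    if date.day is None:
        return CalendarDate(year, month)
    day = min(date.day, calendar.monthrange(year, month)[1])  # clamp
    return CalendarDate(year, month, day)


def apply_offset(reference: IsoValue, spec: RelativeSpec) -> IsoValue:
    """Calendar-aware offset of the reference time by a relative spec.

    The reference must be at least as precise as the unit requires (day
    precision for DAY/WEEK and sub-day units, month for MONTH, year for
    YEAR).  Output precision equals the reference precision; the approx flag
    does not alter the value; SAME returns the reference unchanged.
    """
    if spec.direction == "SAME":
        return reference
    sign = -1 if spec.direction == "BEFORE" else 1
    ref_date = _ref_calendar_date(reference)
    clock = reference if isinstance(reference, ClockTime) else None

    if spec.unit == "YEAR":
        if ref_date.precision == "year":
            return CalendarDate(ref_date.year + sign * spec.magnitude)
        return _shift_months(ref_date, sign * 12 * spec.magnitude)
    if spec.unit == "MONTH":
        if ref_date.precision == "year":
            raise NormalizationError("month offset needs month-precise reference")
        return _shift_months(ref_date, sign * spec.magnitude)

    if ref_date.precision != "day":
        raise NormalizationError(f"{spec.unit} offset needs day-precise reference")
    base = _dt.date(ref_date.year, ref_date.month, ref_date.day)
    if spec.unit in ("DAY", "WEEK"):
        days = spec.magnitude * (7 if spec.unit == "WEEK" else 1)
        shifted = base + _dt.timedelta(days=sign * days)
        out = CalendarDate(shifted.year, shifted.month, shifted.day)
        if clock is not None:
            return ClockTime(out, clock.hour, clock.minute, clock.second)
        return out
    seconds = spec.magnitude * {"HOUR": 3600, "MINUTE": 60, "SECOND": 1}[spec.unit]
    if clock is not None:
        stamp = _dt.datetime(ref_date.year, ref_date.month, ref_date.day,
                             clock.hour, clock.minute, clock.second)
        stamp += _dt.timedelta(seconds=sign * seconds)
        return ClockTime(
            CalendarDate(stamp.year, stamp.month, stamp.day),
            stamp.hour, stamp.minute, stamp.second,
        )
    # sub-day offset against a date-only reference: whole days, rounded down
    shifted = base + _dt.timedelta(days=sign * (seconds // 86400))
    return CalendarDate(shifted.year, shifted.month, shifted.day)


# --------------------------------------------------------------------------
# durations and sets

_DUR_PART = re.compile(
    r"(\d{1,3}|[一二两三四五六七八九十]{1,3})[ \t]?个?(小时|分钟|星期|年|月|周|天|日|秒)"
)
_DUR_FIELD = {
    "YEAR": "years", "MONTH": "months", "WEEK": "weeks", "DAY": "days",
    "HOUR": "hours", "MINUTE": "minutes", "SECOND": "seconds",
}


def normalize_duration(surface: str) -> Duration:
    """Normalize a duration surface; 余/约/多 approximation markers drop
    (``1年余`` -> ``P1Y``), compounds accumulate (``两年五个月`` -> ``P2Y5M``)."""
    surface = surface.strip()
    fields: dict[str, int] = {}
    end = 0
    for m in _DUR_PART.finditer(surface):
        if m.start() != end:
            raise NormalizationError(f"not a duration: {surface!r}")
        end = m.end()
        unit = _UNIT_MAP[m.group(2)]
        fields[_DUR_FIELD[unit]] = fields.get(_DUR_FIELD[unit], 0) + parse_number(m.group(1))
    if not fields or surface[end:] not in ("", "余", "约", "多"):
        raise NormalizationError(f"not a duration: {surface!r}")
    return Duration(**fields)


_SET_RE = re.compile(
    r"^第(\d{1,3}|[一二两三四五六七八九十]{1,3})"
    r"(?:[、,，](\d{1,3}|[一二两三四五六七八九十]{1,3}))*[天日]$"
)
_SET_NUM = re.compile(r"\d{1,3}|[一二两三四五六七八九十]{1,3}")


def normalize_set(surface: str, reference: IsoValue) -> DateSet:
    """Enumerated follow-up days relative to an event date; day one is the
    event day, so 第k天 maps to reference + (k-1) days."""
    surface = surface.strip()
    if _SET_RE.match(surface) is None:
        raise NormalizationError(f"not an enumerated day set: {surface!r}")
    ref_date = _ref_calendar_date(reference)
    if ref_date.precision != "day":
        raise NormalizationError("day set needs a day-precise reference")
    base = _dt.date(ref_date.year, ref_date.month, ref_date.day)
    dates = []
    for token in _SET_NUM.findall(surface[1:-1]):
        k = parse_number(token)
        d = base + _dt.timedelta(days=k - 1)
        dates.append(CalendarDate(d.year, d.month, d.day))
    return DateSet(tuple(dates))


# --------------------------------------------------------------------------
# pattern correction and pipeline assembly


def apply_correction(
    doc: Document,
    tx: Timex3,
    patterns: Sequence[ContextPattern],
    anchor_value: Optional[IsoValue],
) -> Optional[IsoValue]:
    """If a NORM_ANCHOR_EQUALS pattern matches the TE's context, the value is
    overridden with the reference time's value; the longest matching template
    wins.  Returns None when no pattern matches."""
    if anchor_value is None:
        return None
    b, e = tx.span
    best: Optional[ContextPattern] = None
    for pat in patterns:
        if pat.purpose is not PatternPurpose.NORM_ANCHOR_EQUALS:
            continue
        left, right = pat.context()
        if doc.text[max(0, b - len(left)) : b] != left:
            continue
        if doc.text[e : e + len(right)] != right:
            continue
        if best is None or len(pat.key()) > len(best.key()):
            best = pat
    return anchor_value if best is not None else None


def _normalize_one(
    doc: Document,
    tx: Timex3,
    patterns: Sequence[ContextPattern],
    lexicons: anchor_resolver.Lexicons,
) -> tuple[str, Optional[str]]:
    """(value, anchor_tid) for a classified TE within a document whose direct
    TEs are already normalized."""
    if is_direct_surface(tx.surface, tx.ttype):
        return format_iso(normalize_direct(tx.surface, tx.ttype)), None
    if tx.ttype == TimexType.DURATION:
        return format_iso(normalize_duration(tx.surface)), None
    decision = anchor_resolver.resolve(doc, tx, lexicons)
    if not decision.needs_anchor:
        return format_iso(normalize_direct(tx.surface, tx.ttype)), None
    if decision.anchor_value is None:
        raise anchor_resolver.UnresolvedAnchor(tx.tid)
    reference = decision.anchor_value
    if tx.ttype == TimexType.SET:
        value: IsoValue = normalize_set(tx.surface, reference)
    else:
        try:
            value = normalize_partial_date(tx.surface, reference)
        except NormalizationError:
            value = apply_offset(reference, parse_relative(tx.surface))
    corrected = apply_correction(doc, tx, patterns, reference)
    if corrected is not None:
        value = corrected
    return format_iso(value), decision.anchor_tid


def is_direct_surface(surface: str, ttype: TimexType) -> bool:
    return anchor_resolver.is_direct(surface, ttype)


def normalize_document(
    doc: Document,
    model=None,
    patterns: Sequence[ContextPattern] = (),
    lexicons: Optional[anchor_resolver.Lexicons] = None,
    tagger: Optional[TaggerPort] = None,
) -> Document:
    """Normalize a document whose TE spans are already known (e.g. gold
    spans): predict types with ``model`` when given (otherwise keep the
    types on the document), then fill values and anchors.

    Direct TEs are normalized first so they can serve as reference times;
    anaphoric TEs follow in document order.  Per-TE failures are logged and
    leave the Value empty rather than aborting the document.
    """
    lexicons = lexicons or anchor_resolver.default_lexicons()
    tagger = tagger or LexiconTagger()
    out = Document(
        doc_id=doc.doc_id,
        text=doc.text,
        header_events=parse_header_events(doc.text),
        timexes=[
            Timex3(tid=tx.tid, ttype=tx.ttype, value="", span=tx.span, surface=tx.surface)
            for tx in doc.timexes
        ],
    )
    if model is not None:
        from .type_classifier import predict_many

        vectors = [build_vector(out, tx, tagger) for tx in out.timexes]
        for tx, ttype in zip(out.timexes, predict_many(model, vectors)):
            tx.ttype = ttype
    # pass 1: direct TEs
    for tx in out.timexes:
        if is_direct_surface(tx.surface, tx.ttype):
            try:
                tx.value = format_iso(normalize_direct(tx.surface, tx.ttype))
            except NormalizationError as e:
                logger.warning("%s %s: %s", out.doc_id, tx.tid, e)
    # pass 2: everything else, document order
    for tx in out.timexes:
        if tx.value:
            continue
        try:
            tx.value, tx.anchor_tid = _normalize_one(out, tx, patterns, lexicons)
        except (NormalizationError, anchor_resolver.UnresolvedAnchor) as e:
            logger.warning("%s %s: %s", out.doc_id, tx.tid, e)
    return out


def annotate(
    text: str,
    model=None,
    patterns: Sequence[ContextPattern] = (),
    lexicons: Optional[anchor_resolver.Lexicons] = None,
    rules: Optional[Sequence[ExtractionRule]] = None,
    tagger: Optional[TaggerPort] = None,
    doc_id: str = "doc",
) -> Document:
    """Full pipeline on raw text: extract -> classify -> resolve anchors ->
    normalize -> correct.  tids are assigned in document order starting at
    t1; anchorTimeID is set whenever a reference TE was used."""
    extraction_patterns = [
        p for p in patterns if p.purpose is PatternPurpose.EXTRACTION
    ]
    spans = extract_spans(text, rules or default_rules(), extraction_patterns)
    doc = Document(doc_id=doc_id, text=text,
                   header_events=parse_header_events(text))
    for i, (span, surface) in enumerate(spans, start=1):
        # provisional type; the classifier overrides it when a model is given
        doc.timexes.append(
            Timex3(tid=f"t{i}", ttype=TimexType.DATE, value="", span=span, surface=surface)
        )
    return normalize_document(doc, model=model, patterns=patterns,
                              lexicons=lexicons, tagger=tagger)
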