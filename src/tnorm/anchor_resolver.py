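"""Reference-time (anchor) resolution for anaphoric temporal expressions.

A TE like ``6天前`` or ``目前`` cannot be normalized on its own: its value is
computed relative to a reference time.  Three strategies are tried in order:

1. **Critical event** — a clinical milestone mention (入院, 出院, 手术, 化疗,
   返院...) in the same sentence whose occurrence time is known: from a direct
   TE in that sentence, from a structured header line (入院日期/出院日期), or
   from another sentence of the document pairing the event with a direct TE.
2. **Section phrase** — the enclosing paragraph opens with a section header
   (出院医嘱, 入院诊断, 出院情况...) conventionally anchored to a critical
   event's date; e.g. everything under 出院医嘱 is anchored to discharge.
3. **Nearest direct TE** — the nearest preceding already-normalized direct
   TE by character distance between span starts; if none precedes, the
   nearest following one.

Direct TEs (absolute dates/times) and DURATIONs need no anchor.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .extractor import default_rules
from .timex_core import (
    CalendarDate,
    ClockTime,
    Document,
    EventKind,
    IsoValue,
    Timex3,
    TimexType,
    parse_iso,
)

__all__ = [
    "CriticalEventLexicon",
    "SectionPhraseLexicon",
    "Lexicons",
    "AnchorDecision",
    "UnresolvedAnchor",
    "default_lexicons",
    "is_direct",
    "resolve",
]


class UnresolvedAnchor(LookupError):
    """A TE needs a reference time but none could be identified."""

    def __init__(self, tid: str):
        super().__init__(f"no reference time found for {tid}")
        self.tid = tid


@dataclass(frozen=True)
class CriticalEventLexicon:
    """Surface form -> critical event kind (入院 -> ADMISSION, ...)."""

    entries: dict[str, EventKind]


@dataclass(frozen=True)
class SectionPhraseLexicon:
    """Paragraph-opening phrase -> event kind providing the section's
    reference time (出院医嘱 -> DISCHARGE, ...)."""

    entries: dict[str, EventKind]


@dataclass(frozen=True)
class Lexicons:
    events: CriticalEventLexicon
    sections: SectionPhraseLexicon


def default_lexicons() -> Lexicons:
    def _load(name: str) -> dict[str, EventKind]:
        raw = resources.files("tnorm.data").joinpath(name).read_text("utf-8")
        return {k: EventKind(v) for k, v in json.loads(raw).items()}

    return Lexicons(
        events=CriticalEventLexicon(_load("critical_events.json")),
        sections=SectionPhraseLexicon(_load("section_phrases.json")),
    )


@dataclass(frozen=True)
class AnchorDecision:
    needs_anchor: bool
    strategy: str  # CRITICAL_EVENT | SECTION_PHRASE | NEAREST_DIRECT | NONE
    anchor_tid: Optional[str] = None
    anchor_value: Optional[IsoValue] = None


_DIRECT_FAMILIES = ("ABSOLUTE_DATE", "CLOCK_TIME")
# Day/month partial dates like 22/9 need a year from context: not direct.
_PARTIAL_RULE_IDS = ("day_month_slash",)


def is_direct(surface: str, ttype: TimexType) -> bool:
    """True iff the TE normalizes without a reference time: its type is not
    DURATION and the surface is a full absolute date or clock time."""
    if ttype == TimexType.DURATION:
        return False
    for rule in default_rules():
        if rule.family in _DIRECT_FAMILIES and rule.rule_id not in _PARTIAL_RULE_IDS:
            m = rule.matcher.fullmatch(surface)
            if m is not None:
                return True
    return False


def _sentence_bounds(text: str, pos: int) -> tuple[int, int]:
    delims = "。！？；;\n"
    b = pos
    while b > 0 and text[b - 1] not in delims:
        b -= 1
    e = pos
    while e < len(text) and text[e] not in delims:
        e += 1
    return b, e


def _paragraph_bounds(text: str, pos: int) -> tuple[int, int]:
    b = text.rfind("\n", 0, pos) + 1
    e = text.find("\n", pos)
    return b, len(text) if e < 0 else e


def _direct_timexes(doc: Document) -> list[Timex3]:
    return [
        tx
        for tx in doc.timexes
        if tx.value and is_direct(tx.surface, tx.ttype)
    ]


def _event_mentions(doc: Document, lex: CriticalEventLexicon) -> list[tuple[int, str, EventKind]]:
    """(position, surface, kind) of every critical-event mention, leftmost
    and longest-surface first at equal positions."""
    mentions = []
    for surface, kind in lex.entries.items():
        for m in re.finditer(re.escape(surface), doc.text):
            mentions.append((m.start(), surface, kind))
    mentions.sort(key=lambda t: (t[0], -len(t[1])))
    return mentions


def _event_time(
    doc: Document,
    kind: EventKind,
    mention_pos: Optional[int],
    directs: list[Timex3],
    mentions: list[tuple[int, str, EventKind]],
) -> Optional[tuple[Optional[str], IsoValue]]:
    """Occurrence time of a critical event: (anchor tid or None, value).

    Lookup order: a direct TE in the same sentence as the given mention, the
    document header line, then any other sentence pairing the event kind with
    a direct TE.
    """
    if mention_pos is not None:
        sb, se = _sentence_bounds(doc.text, mention_pos)
        in_sentence = [tx for tx in directs if sb <= tx.span[0] < se]
        if in_sentence:
            tx = min(in_sentence, key=lambda t: abs(t.span[0] - mention_pos))
            return tx.tid, parse_iso(tx.value)
    header = doc.header_events.get(kind)
    if header is not None:
        # the header date is normally itself a direct TE; recover its tid
        for tx in directs:
            if _values_equal(parse_iso(tx.value), header):
                return tx.tid, header
        return None, header
    for pos, _surface, k in mentions:
        if k != kind or pos == mention_pos:
            continue
        sb, se = _sentence_bounds(doc.text, pos)
        in_sentence = [tx for tx in directs if sb <= tx.span[0] < se]
        if in_sentence:
            tx = min(in_sentence, key=lambda t: abs(t.span[0] - pos))
            return tx.tid, parse_iso(tx.value)
    return None


def _values_equal(a: IsoValue, b: IsoValue) -> bool:
    if isinstance(a, ClockTime) and isinstance(b, CalendarDate):
        return a.date == b
    if isinstance(b, ClockTime) and isinstance(a, CalendarDate):
        return b.date == a
    return a == b


def resolve(doc: Document, tx: Timex3, lexicons: Optional[Lexicons] = None) -> AnchorDecision:
    """Decide whether ``tx`` needs a reference time and identify it.

    Pure function of (document, TE, lexicons); direct TEs of the document
    must already carry their normalized values.  Raises
    :class:`UnresolvedAnchor` when an anchor is needed but none is found.
    """
    lexicons = lexicons or default_lexicons()
    if tx.ttype == TimexType.DURATION or is_direct(tx.surface, tx.ttype):
        return AnchorDecision(needs_anchor=False, strategy="NONE")
    directs = _direct_timexes(doc)
    mentions = _event_mentions(doc, lexicons.events)

    # 1. critical event in the same sentence, nearest mention first
    sb, se = _sentence_bounds(doc.text, tx.span[0])
    in_sentence = [m for m in mentions if sb <= m[0] < se]
    for pos, _surface, kind in sorted(in_sentence, key=lambda m: abs(m[0] - tx.span[0])):
        found = _event_time(doc, kind, pos, directs, mentions)
        if found is not None:
            tid, value = found
            return AnchorDecision(True, "CRITICAL_EVENT", tid, value)

    # 2. section phrase opening the enclosing paragraph
    pb, pe = _paragraph_bounds(doc.text, tx.span[0])
    paragraph = doc.text[pb:pe]
    for phrase, kind in lexicons.sections.entries.items():
        if paragraph.startswith(phrase) and paragraph[len(phrase) : len(phrase) + 1] in (":", "："):
            found = _event_time(doc, kind, None, directs, mentions)
            if found is not None:
                tid, value = found
                return AnchorDecision(True, "SECTION_PHRASE", tid, value)
            break

    # 3. nearest direct TE: nearest preceding by span start, else following
    preceding = [t for t in directs if t.span[0] < tx.span[0]]
    following = [t for t in directs if t.span[0] > tx.span[0]]
    pick: Optional[Timex3] = None
    if preceding:
        pick = max(preceding, key=lambda t: t.span[0])
    elif following:
        pick = min(following, key=lambda t: t.span[0])
    if pick is not None:
        return AnchorDecision(True, "NEAREST_DIRECT", pick.tid, parse_iso(pick.value))
    raise UnresolvedAnchor(tx.tid)
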