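"""The four temporal feature groups used for TE type prediction.

For each extracted TE surface we collect (1) a bag of part-of-speech tags
from a pluggable tagger, (2) the set of temporal trigger terms it contains
(units like 年/月/天, ordinal 第, direction 前/后, ...), (3) the first
character offset of each trigger within the surface, and (4) a boolean
indicator of clock-time features (colon-separated digit pairs, 点/时 with
digits, day-part words).  The groups are merged into one sparse vector per
TE.

The default tagger is a self-contained lexicon tagger over temporal
vocabulary (digit runs, Chinese numerals, units, day parts, punctuation), so
the package runs offline; any external Chinese POS tagger can be plugged in
through the :class:`TaggerPort` protocol.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

from .timex_core import Document, Timex3, TimexType

__all__ = [
    "TRIGGER_LEXICON",
    "FeatureVector",
    "TaggerPort",
    "LexiconTagger",
    "detect_triggers",
    "time_indicator",
    "build_vector",
    "save_features",
    "load_features",
]

# Trigger lexicon: temporal units and functional characters.
TRIGGER_LEXICON: tuple[str, ...] = (
    "星期", "小时",
    "年", "月", "日", "号", "周", "天", "时", "点", "分", "秒",
    "次", "每", "前", "后", "第",
)

# Deictic atoms are consumed whole and contribute no unit triggers: the 前 of
# 目前 or the 时 of 入院时 is not a temporal unit.
_DEICTIC_ATOMS: tuple[str, ...] = ("目前", "现在", "入院时", "出院时")


class TaggerPort(Protocol):
    """Replaceable component mapping a string to (token, POS-tag) pairs; the
    concatenated tokens must reconstruct the input."""

    def tag(self, text: str) -> list[tuple[str, str]]: ...


class LexiconTagger:
    """Deterministic tagger over the temporal vocabulary of clinical TEs."""

    _LEXEMES: tuple[tuple[str, str], ...] = (
        (r"\d+", "NUM"),
        (r"[零一二两三四五六七八九十]+", "CNUM"),
        (r"上午|下午|凌晨|晚", "DAYPART"),
        (r"目前|现在", "DEICTIC"),
        (r"入院|出院|手术|化疗|返院|回院", "EVENT"),
        (r"星期|小时|分钟", "UNIT"),
        (r"[年月日号周天时点分秒]", "UNIT"),
        (r"第", "ORD"),
        (r"[前后]", "DIR"),
        (r"[余约多]", "APPROX"),
        (r"每", "EVERY"),
        (r"[:：]", "COLON"),
        (r"[、,，./\-]", "PUNCT"),
        (r"\s+", "SPACE"),
    )

    def __init__(self) -> None:
        self._scanner = re.compile(
            "|".join(f"(?P<g{i}>{src})" for i, (src, _) in enumerate(self._LEXEMES))
        )
        self._tags = [tag for _, tag in self._LEXEMES]

    def tag(self, text: str) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        pos = 0
        while pos < len(text):
            m = self._scanner.match(text, pos)
            if m is None:
                # unknown run: consume up to the next known lexeme
                nxt = self._scanner.search(text, pos)
                end = nxt.start() if nxt else len(text)
                out.append((text[pos:end], "OTHER"))
                pos = end
                continue
            out.append((m.group(0), self._tags[int(m.lastgroup[1:])]))
            pos = m.end()
        return out


def detect_triggers(surface: str) -> tuple[frozenset[str], dict[str, int]]:
    """Trigger terms present in a surface and their first character offsets.

    Scanning is left-to-right with longest match first; deictic atoms are
    consumed without producing triggers.
    """
    triggers: set[str] = set()
    positions: dict[str, int] = {}
    i = 0
    while i < len(surface):
        atom = next((a for a in _DEICTIC_ATOMS if surface.startswith(a, i)), None)
        if atom is not None:
            i += len(atom)
            continue
        hit = next((t for t in TRIGGER_LEXICON if surface.startswith(t, i)), None)
        if hit is not None:
            if hit not in triggers:
                triggers.add(hit)
                positions[hit] = i
            i += len(hit)
            continue
        i += 1
    return frozenset(triggers), positions


_TIME_INDICATOR_RE = re.compile(r"\d{1,2}:\d{2}|[点时]\d|上午|下午|凌晨|晚")


def time_indicator(surface: str) -> bool:
    """True iff the surface carries typical clock-time features."""
    return _TIME_INDICATOR_RE.search(surface) is not None


@dataclass
class FeatureVector:
    """Sparse encoding of the four feature groups for one TE."""

    pos_bag: dict[str, int]
    trigger_ids: frozenset[str]
    trigger_positions: dict[str, int]
    time_indicator: bool
    label: Optional[TimexType] = None

    def to_features(self) -> dict[str, float]:
        """Flatten to a sparse name -> value map for vectorization."""
        feats: dict[str, float] = {}
        for tag, count in self.pos_bag.items():
            feats[f"pos={tag}"] = float(count)
        for trig in self.trigger_ids:
            feats[f"trig={trig}"] = 1.0
        for trig, offset in self.trigger_positions.items():
            feats[f"pos@{trig}"] = float(offset)
        if self.time_indicator:
            feats["time_indicator"] = 1.0
        return feats


def build_vector(
    doc: Document, tx: Timex3, tagger: Optional[TaggerPort] = None
) -> FeatureVector:
    """Feature vector of one TE; a pure function of (surface, tagger)."""
    if doc.text[tx.span[0] : tx.span[1]] != tx.surface:
        raise ValueError(f"{tx.tid} does not belong to the document")
    tagger = tagger or LexiconTagger()
    surface = tx.surface
    try:
        tokens = tagger.tag(surface)
    except Exception as e:  # noqa: BLE001 - surfaced with the offending tid
        raise RuntimeError(f"tagger failed on {tx.tid}: {e}") from e
    pos_bag: dict[str, int] = {}
    for _tok, tag in tokens:
        pos_bag[tag] = pos_bag.get(tag, 0) + 1
    trigger_ids, trigger_positions = detect_triggers(surface)
    return FeatureVector(
        pos_bag=pos_bag,
        trigger_ids=trigger_ids,
        trigger_positions=trigger_positions,
        time_indicator=time_indicator(surface),
        label=tx.ttype,
    )


# --------------------------------------------------------------------------
# JSON-lines persistence of feature records


def save_features(
    records: Sequence[tuple[str, str, FeatureVector]], path
) -> None:
    """Write (doc_id, tid, vector) records as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, tid, fv in records:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc_id,
                        "tid": tid,
                        "pos_bag": fv.pos_bag,
                        "trigger_ids": sorted(fv.trigger_ids),
                        "trigger_positions": fv.trigger_positions,
                        "time_indicator": fv.time_indicator,
                        "label": fv.label.value if fv.label else None,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_features(path) -> list[tuple[str, str, FeatureVector]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                (
                    rec["doc_id"],
                    rec["tid"],
                    FeatureVector(
                        pos_bag=rec["pos_bag"],
                        trigger_ids=frozenset(rec["trigger_ids"]),
                        trigger_positions=rec["trigger_positions"],
                        time_indicator=rec["time_indicator"],
                        label=TimexType(rec["label"]) if rec["label"] else None,
                    ),
                )
            )
    return out
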