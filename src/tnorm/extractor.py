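"""Identification of temporal-expression spans in raw Chinese clinical text.

Extraction combines a heuristic rule inventory (shipped as
``data/rules.json`` so deployments can extend it without code changes) with
learned context patterns: a pattern such as ``遂于<TIMEX3>行`` may recover a
span the rules missed by matching its literal contexts around a TE-shaped
chunk.  Overlaps are resolved longest-match-first, ties to the leftmost span,
so the full clock time ``2014/10/11 7:48:16`` beats its embedded date.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .pattern_miner import ContextPattern

__all__ = ["ExtractionRule", "default_rules", "load_rules", "extract_spans"]

RULE_FAMILIES = frozenset(
    {"ABSOLUTE_DATE", "CLOCK_TIME", "RELATIVE", "DURATION", "SET", "DEICTIC"}
)


@dataclass(frozen=True)
class ExtractionRule:
    """One heuristic rule: a compiled unicode regex with a shape family."""

    rule_id: str
    matcher: re.Pattern
    family: str

    def __post_init__(self) -> None:
        if self.family not in RULE_FAMILIES:
            raise ValueError(f"unknown rule family {self.family!r}")


def load_rules(spec: dict) -> list[ExtractionRule]:
    """Build rules from a parsed rules.json structure; the token ``num`` in a
    matcher source is expanded to the shared numeral sub-pattern."""
    numeral = spec.get("numeral", r"\d{1,3}")
    rules = []
    for entry in spec["rules"]:
        source = entry["matcher"].replace("num", numeral)
        rules.append(
            ExtractionRule(
                rule_id=entry["rule_id"],
                matcher=re.compile(source),
                family=entry["family"],
            )
        )
    return rules


def default_rules() -> list[ExtractionRule]:
    raw = resources.files("tnorm.data").joinpath("rules.json").read_text("utf-8")
    return load_rules(json.loads(raw))


# Characters a pattern-recovered TE chunk may consist of: digits, Chinese
# numerals, temporal units and connectives.  Keeps context patterns with an
# open-ended side from swallowing arbitrary narrative text.
_TE_CHUNK = (
    r"[0-9一二两三四五六七八九十年月日号周天时点分秒小钟前后余约多第、星期"
    r"上午下凌晨晚个/:\-\. ]{1,20}"
)


def _rule_matches(text: str, rules: Sequence[ExtractionRule]) -> list[tuple[int, int, int]]:
    found = []
    for order, rule in enumerate(rules):
        for m in rule.matcher.finditer(text):
            if m.end() > m.start():
                found.append((m.start(), m.end(), order))
    return found


def _select(candidates: Iterable[tuple[int, int, int]]) -> list[tuple[int, int]]:
    """Longest-match overlap resolution; ties leftmost, then rule order."""
    chosen: list[tuple[int, int]] = []
    for b, e, _ in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if all(e <= cb or b >= ce for cb, ce in chosen):
            chosen.append((b, e))
    chosen.sort()
    return chosen


def extract_spans(
    text: str,
    rules: Sequence[ExtractionRule],
    patterns: Optional[Sequence["ContextPattern"]] = None,
) -> list[tuple[tuple[int, int], str]]:
    """Return sorted, non-overlapping ``((begin, end), surface)`` TE spans.

    Rules fire first; learned EXTRACTION patterns may then add spans whose
    template contexts match around a TE-shaped chunk, but never displace a
    rule-produced span (monotonicity).
    """
    if not text:
        return []
    spans = _select(_rule_matches(text, rules))
    for pat in patterns or []:
        if getattr(pat, "purpose", None) is not None and pat.purpose.name != "EXTRACTION":
            continue
        left, right = pat.context()
        if not left and not right:
            continue
        chunk_re = re.compile(
            re.escape(left) + "(" + _TE_CHUNK + ")" + re.escape(right)
        )
        for m in chunk_re.finditer(text):
            b, e = m.start(1), m.end(1)
            if all(e <= cb or b >= ce for cb, ce in spans):
                spans.append((b, e))
                spans.sort()
    return [((b, e), text[b:e]) for b, e in spans]
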