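"""Context-pattern learning from an annotated corpus.

A context pattern is a short character template containing exactly one
placeholder token ``<TIMEX3>`` plus adjacent literal context, e.g.
``术后<TIMEX3>返``.  Patterns are mined in six steps: identify annotated
sentences, substitute each annotation by the placeholder, enumerate all
bounded-length substrings containing the placeholder, score each candidate
over the corpus by support (match count) and confidence (correct-match
fraction), keep those at or above the confidence threshold, and reduce the
group by removing any pattern that has a kept substring pattern at least as
confident (the shorter, more general template wins).

Two purposes are supported: EXTRACTION patterns recover TE spans the
heuristic rules miss, and NORM_ANCHOR_EQUALS patterns flag TEs whose correct
normalized value equals the value of their reference time (e.g. "术后3月余,
返院…", where the elapsed-time reading is wrong and the surgery date itself
is the value).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

from .extractor import ExtractionRule, default_rules, extract_spans
from .timex_core import Document, read_timeml, write_timeml

__all__ = [
    "PLACEHOLDER",
    "PatternPurpose",
    "ContextPattern",
    "MinerConfig",
    "substitute_tags",
    "enumerate_candidates",
    "score_patterns",
    "filter_patterns",
    "learn",
    "split_sentences",
    "save_patterns",
    "load_patterns",
]

PLACEHOLDER = "<TIMEX3>"
# Internal single-character stand-in (a private-use codepoint) so the
# placeholder counts as one character for lengths and substring relations.
_SENTINEL = ""

_TAG_RE = re.compile(r"<TIMEX3\b[^>]*>.*?</TIMEX3>", re.DOTALL)

SENTENCE_DELIMITERS = "。！？；\n"


class PatternPurpose(str, Enum):
    EXTRACTION = "EXTRACTION"
    NORM_ANCHOR_EQUALS = "NORM_ANCHOR_EQUALS"


@dataclass(frozen=True)
class ContextPattern:
    """A scored template; confidence is meaningful only when support > 0."""

    template: str
    purpose: PatternPurpose
    support: int = 0
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.template.count(PLACEHOLDER) != 1:
            raise ValueError(
                f"template must contain {PLACEHOLDER} exactly once: {self.template!r}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.confidence}")
        if self.support < 0:
            raise ValueError("negative support")

    def context(self) -> tuple[str, str]:
        """(left, right) literal context around the placeholder."""
        left, _, right = self.template.partition(PLACEHOLDER)
        return left, right

    def key(self) -> str:
        """Template with the placeholder collapsed to one character, for
        length accounting and substring comparisons."""
        return self.template.replace(PLACEHOLDER, _SENTINEL)


@dataclass(frozen=True)
class MinerConfig:
    max_pattern_len: int = 6  # characters; the placeholder counts as one
    threshold: float = 0.8
    sentence_delimiters: str = SENTENCE_DELIMITERS

    def __post_init__(self) -> None:
        if self.max_pattern_len < 1:
            raise ValueError("max_pattern_len must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0,1]")


def split_sentences(text: str, delimiters: str = SENTENCE_DELIMITERS) -> list[str]:
    """Split on the fixed delimiter set, dropping delimiters and empties."""
    return [s for s in re.split("[" + re.escape(delimiters) + "]", text) if s]


def substitute_tags(annotated_sentence: str) -> str:
    """Replace every ``<TIMEX3 ...>surface</TIMEX3>`` annotation (tag plus
    surface) by the bare placeholder token, preserving all other characters."""
    templated, n = _TAG_RE.subn(PLACEHOLDER, annotated_sentence)
    if n == 0:
        raise ValueError("sentence contains no TIMEX3 annotation")
    return templated


def enumerate_candidates(templated: str, cfg: MinerConfig) -> list[str]:
    """All contiguous substrings of a templated sentence that contain exactly
    one placeholder and are at most ``max_pattern_len`` characters long, the
    placeholder counting as a single character.  Enumerated per placeholder
    occurrence, ordered by left extent then right extent, deduplicated."""
    s = templated.replace(PLACEHOLDER, _SENTINEL)
    if _SENTINEL not in s:
        raise ValueError("templated string contains no placeholder")
    seen: set[str] = set()
    out: list[str] = []
    for i, ch in enumerate(s):
        if ch != _SENTINEL:
            continue
        for left in range(i, -1, -1):
            if s[left] == _SENTINEL and left != i:
                break
            if i - left + 1 > cfg.max_pattern_len:
                break
            for right in range(i, len(s)):
                if s[right] == _SENTINEL and right != i:
                    break
                if right - left + 1 > cfg.max_pattern_len:
                    break
                cand = s[left : right + 1]
                if cand not in seen:
                    seen.add(cand)
                    out.append(cand)
    return [c.replace(_SENTINEL, PLACEHOLDER) for c in out]


def _anchor_equal(doc: Document, tx) -> bool:
    if tx.anchor_tid is None or not tx.value:
        return False
    try:
        anchor = doc.by_tid(tx.anchor_tid)
    except KeyError:
        return False
    return bool(anchor.value) and anchor.value == tx.value


def _sites(
    doc: Document,
    purpose: PatternPurpose,
    rules: Optional[Sequence[ExtractionRule]],
) -> list[tuple[int, int, bool]]:
    """(begin, end, correct) scoring sites of one document.

    NORM_ANCHOR_EQUALS sites are the gold TEs; a site is correct when the
    TE's gold value equals its reference time's gold value.  EXTRACTION sites
    are the union of gold spans and rule-extracted spans; a site is correct
    when it coincides with a gold span.
    """
    gold = {tx.span: tx for tx in doc.timexes}
    if purpose is PatternPurpose.NORM_ANCHOR_EQUALS:
        return [(b, e, _anchor_equal(doc, tx)) for (b, e), tx in gold.items()]
    spans = set(gold)
    for span, _surface in extract_spans(doc.text, rules or default_rules()):
        spans.add(span)
    return [(b, e, (b, e) in gold) for b, e in sorted(spans)]


def score_patterns(
    candidates: Sequence[str],
    corpus: Sequence[Union[Document, str]],
    purpose: PatternPurpose,
    rules: Optional[Sequence[ExtractionRule]] = None,
) -> list[ContextPattern]:
    """Validate candidate templates against the corpus.

    support = number of sites where the template's contexts match around the
    site span; confidence = fraction of those sites that are correct for the
    given purpose.  Zero-support candidates are returned with confidence 0
    and are dropped by :func:`filter_patterns`.
    """
    docs = [read_timeml(d, strict=False) if isinstance(d, str) else d for d in corpus]
    if not candidates:
        return []
    by_context: dict[tuple[int, int], set[tuple[str, str]]] = {}
    order: dict[tuple[str, str], int] = {}
    for idx, cand in enumerate(candidates):
        left, _, right = cand.partition(PLACEHOLDER)
        ctx = (left, right)
        if ctx not in order:
            order[ctx] = idx
            by_context.setdefault((len(left), len(right)), set()).add(ctx)
    support: dict[tuple[str, str], int] = {}
    correct: dict[tuple[str, str], int] = {}
    for doc in docs:
        text = doc.text
        for b, e, ok in _sites(doc, purpose, rules):
            for (ll, rl), ctxs in by_context.items():
                if b - ll < 0 or e + rl > len(text):
                    continue
                ctx = (text[b - ll : b], text[e : e + rl])
                if ctx in ctxs:
                    support[ctx] = support.get(ctx, 0) + 1
                    if ok:
                        correct[ctx] = correct.get(ctx, 0) + 1
    out = []
    for ctx, idx in sorted(order.items(), key=lambda kv: kv[1]):
        sup = support.get(ctx, 0)
        conf = correct.get(ctx, 0) / sup if sup else 0.0
        out.append(
            ContextPattern(
                template=ctx[0] + PLACEHOLDER + ctx[1],
                purpose=purpose,
                support=sup,
                confidence=conf,
            )
        )
    return out


def filter_patterns(
    patterns: Sequence[ContextPattern], cfg: MinerConfig
) -> list[ContextPattern]:
    """Threshold filtering then substring reduction.

    Keeps patterns with confidence >= threshold and support >= 1; then a
    pattern is removed when another kept pattern is a strict substring of its
    template with at least its confidence (the more general template wins
    unless the longer one is strictly more confident).  Result sorted by
    (confidence desc, support desc, template).
    """
    kept = [p for p in patterns if p.support >= 1 and p.confidence >= cfg.threshold]
    reduced = []
    for p in kept:
        pk = p.key()
        dominated = any(
            q is not p and q.key() != pk and q.key() in pk and q.confidence >= p.confidence
            for q in kept
        )
        if not dominated:
            reduced.append(p)
    return sorted(reduced, key=lambda p: (-p.confidence, -p.support, p.template))


def learn(
    corpus: Sequence[Union[Document, str]],
    cfg: MinerConfig,
    purpose: PatternPurpose,
    rules: Optional[Sequence[ExtractionRule]] = None,
    apply_filter: bool = True,
) -> list[ContextPattern]:
    """Full mining pipeline: split -> substitute -> enumerate -> score ->
    filter.  ``apply_filter=False`` stops after scoring, exposing the raw
    candidate set (e.g. the fifteen candidates of a single short sentence)."""
    docs = [read_timeml(d, strict=False) if isinstance(d, str) else d for d in corpus]
    candidates: list[str] = []
    seen: set[str] = set()
    for doc in docs:
        annotated = write_timeml(doc)
        for sentence in split_sentences(annotated, cfg.sentence_delimiters):
            if _TAG_RE.search(sentence) is None:
                continue
            for cand in enumerate_candidates(substitute_tags(sentence), cfg):
                if cand not in seen:
                    seen.add(cand)
                    candidates.append(cand)
    scored = score_patterns(candidates, docs, purpose, rules)
    return filter_patterns(scored, cfg) if apply_filter else scored


# --------------------------------------------------------------------------
# TSV persistence: template \t purpose \t support \t confidence


def save_patterns(patterns: Sequence[ContextPattern], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in patterns:
            fh.write(f"{p.template}\t{p.purpose.value}\t{p.support}\t{p.confidence:.6f}\n")


def load_patterns(path) -> list[ContextPattern]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            template, purpose, support, confidence = line.split("\t")
            out.append(
                ContextPattern(
                    template=template,
                    purpose=PatternPurpose(purpose),
                    support=int(support),
                    confidence=float(confidence),
                )
            )
    return out
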