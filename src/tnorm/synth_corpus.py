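"""Seeded synthetic Chinese discharge summaries with gold TIMEX3 annotations.

The private hospital corpus behind this task cannot be shipped, so every
stage is exercised on generated documents that emulate its temporal
structure: structured header lines (入院日期/出院日期), section paragraphs
(入院诊断, 出院情况, 出院医嘱), critical-event sentences pairing 手术/化疗
with direct dates, and a realistic mix of absolute dates, clock times,
durations, relative expressions, deictics and enumerated day sets —
averaging ~13.4 TEs per document.  Generation is template-based so the gold
Type/Value/anchorTimeID attributes are correct by construction.

Two noise knobs reproduce documented failure modes of real summaries:
``typo_rate`` corrupts the discharge header line to ``出院日期:出院日期``
(losing the discharge reference time), and ``planted_pattern_rate`` inserts
anchor-equal contexts ``术后<TE>返院复查`` in which the correct value of the
elapsed-time TE equals its reference time — the case the learned
normalization patterns exist to fix.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .timex_core import (
    Document,
    Timex3,
    TimexType,
    parse_header_events,
    write_timeml,
)

__all__ = ["GenConfig", "generate", "write_corpus"]

PLANTED_TEMPLATE = "术后<TIMEX3>返"  # context planted around anchor-equal TEs


@dataclass(frozen=True)
class GenConfig:
    n_docs: int = 100
    seed: int = 0
    mean_tes_per_doc: float = 13.4
    type_mix: tuple[float, float, float, float] = (0.70, 0.10, 0.15, 0.05)
    # probabilities over (DATE, TIME, DURATION, SET) for the sampled extras
    anaphoric_fraction: float = 0.3
    typo_rate: float = 0.05
    planted_pattern_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be positive")
        if self.mean_tes_per_doc <= 0:
            raise ValueError("mean_tes_per_doc must be positive")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        for rate in (self.anaphoric_fraction, self.typo_rate, self.planted_pattern_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")


# ---------------------------------------------------------------------------
# small calendar helpers, independent of the normalizer's arithmetic

def _iso(d: _dt.date) -> str:
    return d.isoformat()


def _shift_months(d: _dt.date, months: int) -> _dt.date:
    total = d.year * 12 + (d.month - 1) + months
    year, month = divmod(total, 12)
    last = [31, 29 if calendar_leap(year) else 28, 31, 30, 31, 30,
            31, 31, 30, 31, 30, 31][month]
    return _dt.date(year, month + 1, min(d.day, last))


def calendar_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass
class _TE:
    """One gold TE while a document is being assembled."""

    surface: str
    ttype: TimexType
    value: str
    direct: bool = False
    anchor_ref: Optional[str] = None  # symbolic: ADM, DIS, SRG, CHEMO, NEAREST
    offset: int = -1  # filled during assembly
    tid: str = ""


_CN_DIGITS = "零一二三四五六七八九"


def _cn(n: int) -> str:
    if n < 10:
        return "两" if n == 2 else _CN_DIGITS[n]
    tens, units = divmod(n, 10)
    out = ("" if tens == 1 else _CN_DIGITS[tens]) + "十"
    return out + (_CN_DIGITS[units] if units else "")


def _fmt_date(d: _dt.date, style: int) -> tuple[str, str]:
    """(surface, gold value) of a direct date in one of three house styles."""
    if style == 0:
        return f"{d.year}年{d.month}月{d.day}日", _iso(d)
    if style == 1:
        return _iso(d), _iso(d)
    return f"{d.year}/{d.month}/{d.day}", _iso(d)


class _DocBuilder:
    """Accumulates literal text and TE records, then assembles a Document
    with spans, document-order tids and symbolic anchors resolved."""

    def __init__(self) -> None:
        self.parts: list = []  # str literals and _TE records
        self.role_tids: dict[str, str] = {}  # ADM/DIS/SRG/CHEMO -> tid

    def text(self, s: str) -> None:
        self.parts.append(s)

    def te(self, te: _TE) -> None:
        self.parts.append(te)

    def last_direct_value(self) -> Optional[str]:
        for part in reversed(self.parts):
            if isinstance(part, _TE) and part.direct and part.value:
                return part.value
        return None

    def assemble(self, doc_id: str) -> Document:
        chunks: list[str] = []
        offset = 0
        tes: list[_TE] = []
        for part in self.parts:
            if isinstance(part, str):
                chunks.append(part)
                offset += len(part)
            else:
                part.offset = offset
                part.tid = f"t{len(tes) + 1}"
                tes.append(part)
                chunks.append(part.surface)
                offset += len(part.surface)
        text = "".join(chunks)
        timexes = [
            Timex3(
                tid=te.tid,
                ttype=te.ttype,
                value=te.value,
                span=(te.offset, te.offset + len(te.surface)),
                surface=te.surface,
                anchor_tid=self.role_tids.get(te.anchor_ref)
                if te.anchor_ref is not None
                else None,
            )
            for te in tes
        ]
        return Document(
            doc_id=doc_id,
            text=text,
            timexes=timexes,
            header_events=parse_header_events(text),
        )


def _sample_extra(
    rng: np.random.Generator,
    cfg: GenConfig,
    adm: _dt.date,
    chemo: _dt.date,
    allow_imprecise: bool,
) -> tuple[str, list]:
    """One extra sentence: returns (section, parts) where section is
    'diag' (入院诊断 paragraph) or 'advice' (出院医嘱 paragraph)."""
    kind = ("DATE", "TIME", "DURATION", "SET")[
        int(rng.choice(4, p=list(cfg.type_mix)))
    ]
    if kind == "SET":
        a = int(rng.integers(2, 10))
        b = a + int(rng.integers(1, 8))
        surface = f"第{a}、{b}天"
        dates = [chemo + _dt.timedelta(days=k - 1) for k in (a, b)]
        value = "[" + ",".join(_iso(d) for d in dates) + "]"
        te = _TE(surface, TimexType.SET, value, anchor_ref="CHEMO")
        return "advice", ["化疗后", te, "复查肝功能"]
    if kind == "TIME":
        day = adm - _dt.timedelta(days=int(rng.integers(1, 30)))
        h, mi, s = (int(rng.integers(6, 12)), int(rng.integers(0, 60)),
                    int(rng.integers(0, 60)))
        if rng.random() < 0.5:
            surface = f"{day.year}/{day.month}/{day.day} {h}:{mi:02d}:{s:02d}"
        else:
            surface = f"{day.year}年{day.month}月{day.day}日上午{h}点{mi}分{s}秒"
        value = f"{_iso(day)}T{h:02d}:{mi:02d}:{s:02d}"
        te = _TE(surface, TimexType.TIME, value, direct=True)
        return "diag", ["患者于", te, "接受检查"]
    if kind == "DURATION":
        roll = rng.random()
        if roll < 0.3:
            n = int(rng.integers(1, 6))
            surface, value = f"{n}年余", f"P{n}Y"
        elif roll < 0.55:
            y, m = int(rng.integers(1, 4)), int(rng.integers(1, 10))
            surface, value = f"{_cn(y)}年{_cn(m)}个月", f"P{y}Y{m}M"
        elif roll < 0.8:
            m = int(rng.integers(1, 10))
            surface, value = f"{_cn(m)}个月", f"P{m}M"
        else:
            w = int(rng.integers(1, 5))
            surface, value = f"{_cn(w)}周", f"P{w}W"
        te = _TE(surface, TimexType.DURATION, value)
        verb = "发现肿物" if rng.random() < 0.5 else "病程"
        return "diag", [verb, te]
    # DATE extras: anaphoric (relative / day-month) or absolute
    if rng.random() < cfg.anaphoric_fraction:
        roll = rng.random()
        if roll < 0.45:
            n = int(rng.integers(1, 30))
            surface = f"{n}天前"
            value = _iso(adm - _dt.timedelta(days=n))
        elif roll < 0.7:
            n = int(rng.integers(1, 9))
            surface = f"{n}周前"
            value = _iso(adm - _dt.timedelta(weeks=n))
        elif roll < 0.9:
            n = int(rng.integers(1, 12))
            surface = f"{_cn(n)}个月前"
            value = _iso(_shift_months(adm, -n))
        else:
            # day/month form like 22/9; day kept > 12 so the order is
            # unambiguous, <= 28 so it is valid in any month of any year
            d = adm - _dt.timedelta(days=int(rng.integers(30, 300)))
            day = min(d.day if d.day > 12 else d.day + 13, 28)
            surface = f"{day}/{d.month}"
            value = _iso(_dt.date(adm.year, d.month, day))
        te = _TE(surface, TimexType.DATE, value, anchor_ref="ADM")
        if surface.endswith("前"):
            return "diag", ["患者", te, "出现疼痛"]
        return "diag", ["于", te, "复查血象"]
    d = adm - _dt.timedelta(days=int(rng.integers(1, 300)))
    surface, value = _fmt_date(d, int(rng.integers(0, 3)))
    te = _TE(surface, TimexType.DATE, value, direct=True)
    if not allow_imprecise:
        return "diag", ["患者于", te, "行乳腺B超检查"]
    roll = rng.random()
    if roll < 0.15:
        te = _TE(f"{d.year}年{d.month}月", TimexType.DATE,
                 f"{d.year:04d}-{d.month:02d}", direct=True)
    elif roll < 0.2:
        te = _TE(f"{d.year}年", TimexType.DATE, f"{d.year:04d}", direct=True)
    return "diag", ["患者于", te, "行乳腺B超检查"]


def generate(cfg: GenConfig) -> list[Document]:
    """Generate the corpus; deterministic and byte-identical per seed."""
    rng = np.random.default_rng(cfg.seed)
    expected_skeleton = 7.0 - cfg.typo_rate + cfg.planted_pattern_rate
    lam = max(0.0, cfg.mean_tes_per_doc - expected_skeleton)
    docs = []
    for i in range(cfg.n_docs):
        docs.append(_generate_doc(rng, cfg, f"synth-{i:04d}", lam))
    return docs


def _generate_doc(
    rng: np.random.Generator, cfg: GenConfig, doc_id: str, lam: float
) -> Document:
    adm = _dt.date(
        int(rng.integers(2012, 2017)),
        int(rng.integers(1, 13)),
        int(rng.integers(1, 29)),
    )
    srg = adm + _dt.timedelta(days=int(rng.integers(1, 5)))
    chemo = srg + _dt.timedelta(days=int(rng.integers(1, 5)))
    dis = chemo + _dt.timedelta(days=int(rng.integers(2, 10)))
    typo = rng.random() < cfg.typo_rate
    planted = rng.random() < cfg.planted_pattern_rate
    n_extra = int(rng.poisson(lam))
    extras = [
        _sample_extra(rng, cfg, adm, chemo, allow_imprecise=not typo)
        for _ in range(n_extra)
    ]

    b = _DocBuilder()
    tes: list[_TE] = []

    def add(te: _TE, role: Optional[str] = None) -> _TE:
        b.te(te)
        tes.append(te)
        if role is not None:
            b.role_tids[role] = f"t{len(tes)}"
        return te

    # tids follow document order; role_tids relies on add() being called in
    # the same order the parts are emitted.
    adm_surface, adm_value = _fmt_date(adm, int(rng.integers(0, 2)))
    b.text("入院日期:")
    add(_TE(adm_surface, TimexType.DATE, adm_value, direct=True), role="ADM")
    b.text("\n出院日期:")
    if typo:
        b.text("出院日期\n")
    else:
        dis_surface, dis_value = _fmt_date(dis, int(rng.integers(0, 2)))
        add(_TE(dis_surface, TimexType.DATE, dis_value, direct=True), role="DIS")
        b.text("\n")

    # 入院诊断 paragraph: diagnosis plus sampled history sentences
    b.text("入院诊断:右乳腺癌")
    for section, parts in extras:
        if section != "diag":
            continue
        b.text("。")
        for part in parts:
            if isinstance(part, _TE):
                add(part)
            else:
                b.text(part)
    b.text("。\n")

    # critical-event sentences: surgery and chemotherapy with direct dates
    srg_surface, srg_value = _fmt_date(srg, int(rng.integers(0, 3)))
    b.text("患者于")
    add(_TE(srg_surface, TimexType.DATE, srg_value, direct=True), role="SRG")
    b.text("行手术治疗。")
    if planted:
        n = int(rng.integers(2, 10))
        b.text("术后")
        add(_TE(f"{n}月余", TimexType.DATE, srg_value, anchor_ref="SRG"))
        b.text("返院复查。")
    b.text("\n患者于")
    chemo_surface, chemo_value = _fmt_date(chemo, int(rng.integers(0, 3)))
    add(_TE(chemo_surface, TimexType.DATE, chemo_value, direct=True), role="CHEMO")
    b.text("行化疗。\n")

    # 出院情况: deictic anchored to the discharge date (or, when the header
    # is corrupted, to the nearest preceding direct TE)
    b.text("出院情况:")
    if typo:
        ref = b.last_direct_value()
        deictic_value = ref if ref else ""
        anchor = "NEAREST"
    else:
        deictic_value = _iso(dis)
        anchor = "DIS"
    te = add(_TE("目前", TimexType.DATE, deictic_value, anchor_ref=anchor))
    b.text("患者恢复良好,准予出院。\n")

    # 出院医嘱: chemotherapy day set and an hour offset from discharge
    b.text("出院医嘱:化疗后")
    a_day = int(rng.integers(2, 10))
    b_day = a_day + int(rng.integers(1, 6))
    c_day = b_day + int(rng.integers(1, 6))
    set_dates = [chemo + _dt.timedelta(days=k - 1) for k in (a_day, b_day, c_day)]
    add(
        _TE(
            f"第{a_day}、{b_day}、{c_day}天",
            TimexType.SET,
            "[" + ",".join(_iso(d) for d in set_dates) + "]",
            anchor_ref="CHEMO",
        )
    )
    b.text("复查血象；")
    for section, parts in extras:
        if section != "advice":
            continue
        for part in parts:
            if isinstance(part, _TE):
                add(part)
            else:
                b.text(part)
        b.text("；")
    hours = int(rng.choice([24, 48, 72]))
    if typo:
        ref = b.last_direct_value()
        base = _dt.date.fromisoformat(ref)
    else:
        base = dis
    add(
        _TE(
            f"{hours}小时后",
            TimexType.DATE,
            _iso(base + _dt.timedelta(days=hours // 24)),
            anchor_ref="NEAREST" if typo else "DIS",
        )
    )
    b.text("自行拆除绷带。\n")

    # resolve NEAREST anchors to the tid of the nearest preceding direct TE
    doc = b.assemble(doc_id)
    _fix_nearest_anchors(doc, tes)
    return doc


def _fix_nearest_anchors(doc: Document, tes: list[_TE]) -> None:
    for i, te in enumerate(tes):
        if te.anchor_ref == "NEAREST":
            for j in range(i - 1, -1, -1):
                if tes[j].direct and tes[j].value:
                    doc.timexes[i].anchor_tid = doc.timexes[j].tid
                    break


def write_corpus(docs: list[Document], out_dir: str) -> str:
    """Write inline-TimeML files plus a manifest JSON; returns the manifest
    path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for doc in docs:
        path = os.path.join(out_dir, f"{doc.doc_id}.xml")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(write_timeml(doc))
        entries.append({"doc_id": doc.doc_id, "file": os.path.basename(path),
                        "n_timexes": len(doc.timexes)})
    manifest = os.path.join(out_dir, "manifest.json")
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump({"documents": entries}, fh, ensure_ascii=False, indent=2)
    return manifest
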