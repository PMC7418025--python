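# Methods

## Task and representation

A temporal expression (TE) in a clinical narrative is represented as a
triple: its surface mention, its TimeML type (DATE, TIME, DURATION, SET),
and its normalized ISO 8601 value. Annotations are inline `<TIMEX3>` tags
with attributes `tid`, `Type`, `Value` and the optional `anchorTimeID`
naming the reference TE a relative value was computed from. Values are one
of: a calendar date at year, month or day precision (`2014`, `2014-06`,
`2014-06-03`); a clock time, optionally date-bearing
(`2014-06-03T07:20:04`); a duration (`P2Y5M`); or a date set, serialized as
a bracketed list of dates (`[2014-09-07,2014-09-10,2014-09-14]`). The date
set serialization is this package's own convention — published material on
this task does not fix a usable SET format. The parser accepts unpadded
months and days (`2014-2`); the writer always zero-pads. Pure-week
durations keep the `W` designator; weeks mixed with other components are
converted to days, since ISO 8601 forbids combining them. No time zones.

## Extraction

The rule inventory (shipped as `data/rules.json`, regex sources expanded
with a shared numeral sub-pattern) covers the surface families observed in
discharge summaries: absolute dates (`2014年6月3日`, `2014-06-03`,
`2014/6/3`, year- and month-precision variants, and the day/month form
`22/9`); clock times with optional date and day-part word (`上午7点20分4秒`,
`7:48:16`); relative offsets `N单位前/后` with Arabic or Chinese numerals
and units 年/月/周/天/日/小时/分钟; durations, including compounds
(`两年五个月`) and approximation markers (`1年余`); enumerated day sets
(`第7、10、14天`); and the deictic atoms 目前/现在/入院时/出院时. Chinese
numerals are recognized to 99; larger magnitudes require digits. Overlaps
resolve longest-match-first, ties leftmost, so a full clock time absorbs its
embedded date. Learned extraction patterns can add spans the rules miss: a
pattern's literal contexts are matched around a TE-shaped chunk (a bounded
run over the temporal alphabet), and pattern spans never displace rule
spans.

Two deliberate narrowing choices: bare 现 and 今 are not extracted as
deictics (they fire inside ordinary words such as 发现; deployments that
want them can add one line to `rules.json`), and `第N次` ordinal-of-event
mentions are not treated as TEs — enumerated sets are day-based only, which
matches how such phrases are annotated in the examples this design follows.

## Type prediction

Four feature groups are computed per TE surface: (1) a bag of
part-of-speech tags from a pluggable tagger — the default is a
self-contained lexicon tagger over temporal vocabulary (digit runs, Chinese
numerals, units, day parts, event words, punctuation) so everything runs
offline, with `TaggerPort` as the seam for an external Chinese tagger; (2)
trigger terms from a fixed lexicon (年 月 日 号 周 星期 天 小时 时 点 分 秒
次 每 前 后 第), matched longest-first with deictic atoms consumed whole so
the 前 of 目前 is not a trigger; (3) trigger positions, taken as the first
character offset of each trigger in the surface — the simplest
deterministic reading of "relative position"; (4) a boolean clock-time
indicator (colon-separated digit pairs, 点/时 followed by a digit, day-part
words). POS features cover the surface only, not its context; the context
window of the original design is not recoverable and the surface-only
encoding already separates the synthetic benchmark.

The default classifier mirrors a randomizable filtered classifier: a seeded
Gaussian random projection of the sparse vectors to 32 dimensions (the
original dimensionality is unpublished; 32 is this package's default, and an
identity projection is available as the limit in which the model coincides
with plain KNN) followed by 1-nearest-neighbor with Euclidean distance and
ties broken by the smallest training index. Logistic regression and an
AdaBoost decision-stump ensemble are registered alternatives. Everything is
bit-reproducible given (data, config, seed). Cross-validation shuffles with
the given seed and stratifies when every class has at least `folds`
members.

## Reference-time resolution

A TE is *direct* when its type is not DURATION and its surface is a full
absolute date or clock time; direct TEs and durations need no reference.
For the rest, three strategies apply in order:

1. **Critical event**: the nearest event mention (入院 出院 手术 术后 化疗
   返院 回院) in the TE's sentence whose occurrence time is known. An
   event's time is looked up as: a direct TE in the same sentence as the
   mention, then the structured header line (入院日期/出院日期), then any
   other sentence pairing that event kind with a direct TE.
2. **Section phrase**: the enclosing paragraph (newline-delimited) opens
   with a known section header followed by a colon (入院诊断/入院情况 →
   admission; 出院诊断/出院情况/出院医嘱 → discharge), and that event's time
   is known.
3. **Nearest direct TE**: the nearest preceding direct TE by character
   distance between span starts; if none precedes, the nearest following.

Both lexicons ship as editable JSON. Failure raises `UnresolvedAnchor`; the
pipeline catches it per TE, logs a warning and emits an empty value rather
than aborting the document.

## Normalization

Relative surfaces parse to (magnitude, unit, direction, approx): 前 is
BEFORE, 后 is AFTER, deictics are SAME, and a bare elapsed-time surface
(3月余, no direction marker) reads as AFTER its reference event. Offsets are
calendar-aware: month and year offsets clamp the day-of-month (one month
before 2014-03-31 is 2014-02-28); day and week offsets are exact; sub-day
offsets against a date-only reference round down to whole days, so 72小时后
a discharge date is +3 days. Output precision equals the reference
precision. The approximation marker 余/约 never changes the value (P1Y for
1年余; no MOD attribute). Partial dates complete from the reference: 22/9
takes the reference year at day precision; a bare month name (2月 typed
DATE) takes the reference year at month precision, same-year reading. Day
sets count the event day as day one: 第k天 is reference + (k−1) days — an
explicit convention, since the day-index origin is not fixed anywhere
authoritative.

## Pattern learning

Context patterns are short character-level templates containing exactly one
`<TIMEX3>` placeholder, mined in six steps: sentence splitting on a fixed
delimiter set (。！？；and newline); substitution of each annotation by the
placeholder; enumeration of every substring containing the placeholder up to
`max_pattern_len` = 6 characters, the placeholder counting as one — the
unique small calibration under which the sentence
遂于`<TIMEX3>`行右乳癌改良根治术 (two left-context and nine right-context
characters) yields exactly 6+5+4 = 15 candidates; scoring over the corpus
(support = matching sites, confidence = correct fraction, where a
normalization site is correct when the TE's gold value equals its reference
time's gold value, and an extraction site — drawn from gold spans plus
rule-extracted spans — is correct when it coincides with a gold span);
threshold filtering at confidence ≥ 0.8 (inclusive); and substring
reduction, under which a pattern is removed when a kept strict substring of
it is at least as confident — the shorter, more general template wins
unless the longer one is strictly better. The published account of the
reduction step is ambiguous about its direction; generality was chosen and
is exercised by the planted-pattern recovery test, which accordingly
accepts the planted template or any fully-confident substring of it. At
application time the longest matching template wins and the TE's value is
replaced by its reference time's value; this reproduces both the intended
correction (术后3月余,返院…) and the documented over-matching failure mode.

## Synthetic corpus

Template-based generation (no language model), so gold annotations are
correct by construction. Each document has header date lines, an admission
→ surgery → chemotherapy → discharge event chain with plausible intervals,
section paragraphs, and a skeleton of seven TEs (two header dates, surgery
and chemotherapy dates, a deictic 目前, a chemotherapy day set, an hour
offset from discharge); additional sentences are sampled to reach a mean of
13.4 TEs per document, matching the reported per-text density of real
discharge summaries. The sampled extras follow a configurable type mix,
default DATE 0.70 / TIME 0.10 / DURATION 0.15 / SET 0.05 — invented
defaults, since per-type counts for the real corpus are unpublished — and a
0.3 anaphoric fraction among extra DATEs. `typo_rate` corrupts the
discharge header to 出院日期:出院日期, which removes the discharge reference
and exercises the nearest-direct fallback (gold values in corrupted
documents follow that fallback, so the corruption displaces the anchoring
strategy rather than making gold unreachable). `planted_pattern_rate`
inserts 术后`N月余`返院复查 sentences whose TE's gold value equals the
surgery date — the anchor-equal case the pattern learner must recover.
Generation is driven by one seeded generator and is byte-identical per
seed.

What the generator does not emulate: lexical variety beyond its sentence
templates, extraction-level ambiguity (every gold span is rule-coverable by
design, so extraction recall near 1.0 on synthetic text says nothing about
recall on real narratives), annotation disagreement, and type ambiguity of
the 肿物增大2月 kind where the same surface is a duration in one context
and a month name in another. Perfect synthetic scores therefore validate
the machinery — span arithmetic, anchoring, calendar computation, pattern
scoring — not real-corpus performance, which on the private corpus this
task was designed around sits near F1 0.84 for full normalization.

## Evaluation

Type prediction uses macro-averaged precision, recall and F1 over the
classes present in gold; zero-denominator per-class ratios count as 0, and
macro-F1 is the mean of per-class F1 (the harmonic-of-means alternative is
available behind `mf_mode="harmonic"`; the published equations are not
printed legibly enough to settle the convention). Normalization uses the
exact-match criterion: #C_value is the number of predicted TEs whose span
and value both equal a gold TE, precision divides by the TEs the system
normalized (empty-value emissions do not count), recall by the gold count.
The ablation metric is accuracy on gold spans — Type and Value both right —
which isolates normalization from extraction. The benchmark harness
generates a corpus, trains patterns and the classifier on the first half,
and reports held-out exact-match P/R/F1, classifier macro metrics, and
rule-only versus rule+pattern accuracy; the acceptance script runs it at
450 documents (≈3,000 held-out TEs), a size chosen to estimate these
proportions to well under a point while remaining a desk-scale computation.

## Known limitations

Errors propagate forward through the three stages, as in any sequential
design: a typed-classification error selects the wrong normalization rule.
The extraction rule inventory is a reconstruction from printed examples,
not a validated clinical ruleset. Anchor resolution assumes
paragraph-structured summaries with colon-terminated section headers.
Fuzzy quantities (数天, "a few days"), TimeML MOD/quant attributes, event
(`<EVENT>`/`<TLINK>`) annotation and cross-document anchoring are out of
scope.
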