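"""Evaluation metrics and the end-to-end benchmark harness.

Type prediction is scored with macro-averaged precision/recall/F1 so that
rare classes (SET is far rarer than DATE in discharge summaries) weigh as
much as frequent ones.  Normalization is scored with the exact-match
criterion: a predicted TE counts only when both its span and its normalized
value are identical to a gold annotation; precision divides by the number of
TEs the system normalized (#N_TE1), recall by the number that should be
normalized (#N_TE2).  The accuracy metric evaluates normalization on gold
spans only (no extraction involved): a gold TE is correct when both its
predicted Type and Value are right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .timex_core import Document

__all__ = [
    "EvalReport",
    "macro_metrics",
    "normalization_prf",
    "normalization_accuracy",
    "run_benchmark",
]


@dataclass
class EvalReport:
    """Per-class and macro classification metrics plus exact-match
    normalization metrics.  Unused groups are left at None/empty."""

    per_class: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    MP: Optional[float] = None
    MR: Optional[float] = None
    MF: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    accuracy: Optional[float] = None
    counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "per_class": {k: list(v) for k, v in self.per_class.items()},
            "counts": dict(self.counts),
        }
        for name in ("MP", "MR", "MF", "precision", "recall", "f1", "accuracy"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        return out


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def macro_metrics(
    gold_labels: Sequence, pred_labels: Sequence, mf_mode: str = "mean_f1"
) -> tuple[float, float, float, dict[str, tuple[float, float, float]]]:
    """Macro-averaged precision, recall and F1 over the labels present in
    gold.  Zero-denominator per-class ratios count as 0.  ``mf_mode`` selects
    the macro-F1 convention: "mean_f1" (mean of per-class F1, default) or
    "harmonic" (harmonic mean of MP and MR)."""
    if len(gold_labels) != len(pred_labels):
        raise ValueError("label sequences differ in length")
    if not gold_labels:
        raise ValueError("empty label sequences")
    classes = sorted({str(g) for g in gold_labels})
    per_class: dict[str, tuple[float, float, float]] = {}
    for k in classes:
        tp = sum(1 for g, p in zip(gold_labels, pred_labels) if str(g) == k and str(p) == k)
        n_pred = sum(1 for p in pred_labels if str(p) == k)
        n_gold = sum(1 for g in gold_labels if str(g) == k)
        p_k = tp / n_pred if n_pred else 0.0
        r_k = tp / n_gold if n_gold else 0.0
        per_class[k] = (p_k, r_k, _f1(p_k, r_k))
    mp = sum(v[0] for v in per_class.values()) / len(classes)
    mr = sum(v[1] for v in per_class.values()) / len(classes)
    if mf_mode == "mean_f1":
        mf = sum(v[2] for v in per_class.values()) / len(classes)
    elif mf_mode == "harmonic":
        mf = _f1(mp, mr)
    else:
        raise ValueError(f"unknown mf_mode {mf_mode!r}")
    return mp, mr, mf, per_class


def _as_docs(x: Union[Document, Sequence[Document]]) -> list[Document]:
    return [x] if isinstance(x, Document) else list(x)


def normalization_prf(
    gold: Union[Document, Sequence[Document]],
    pred: Union[Document, Sequence[Document]],
) -> EvalReport:
    """Exact-match normalization precision/recall/F1 (micro over documents)."""
    gold_docs, pred_docs = _as_docs(gold), _as_docs(pred)
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and predicted document lists differ in length")
    c_value = n_te1 = n_te2 = 0
    for g, p in zip(gold_docs, pred_docs):
        if g.text != p.text:
            raise ValueError(f"document text mismatch for {g.doc_id}")
        gold_map = {tx.span: tx.value for tx in g.timexes}
        n_te2 += len(g.timexes)
        for tx in p.timexes:
            if not tx.value:
                continue  # emitted but not normalized
            n_te1 += 1
            if gold_map.get(tx.span) == tx.value:
                c_value += 1
    precision = c_value / n_te1 if n_te1 else 0.0
    recall = c_value / n_te2 if n_te2 else 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        counts={"C_value": c_value, "N_TE1": n_te1, "N_TE2": n_te2},
    )


def normalization_accuracy(
    gold: Union[Document, Sequence[Document]],
    pred: Union[Document, Sequence[Document]],
) -> EvalReport:
    """Accuracy = #Correct / #N_TE on gold spans; a TE is correct only when
    both its Type and its Value match the gold annotation."""
    gold_docs, pred_docs = _as_docs(gold), _as_docs(pred)
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and predicted document lists differ in length")
    n_correct = n_te = 0
    for g, p in zip(gold_docs, pred_docs):
        pred_map = {tx.span: tx for tx in p.timexes}
        for gtx in g.timexes:
            n_te += 1
            ptx = pred_map.get(gtx.span)
            if ptx is not None and ptx.ttype == gtx.ttype and ptx.value == gtx.value:
                n_correct += 1
    return EvalReport(
        accuracy=n_correct / n_te if n_te else 0.0,
        counts={"Correct": n_correct, "N_TE": n_te},
    )


def run_benchmark(
    seed: int = 1,
    n_docs: int = 450,
    typo_rate: float = 0.0,
    planted_pattern_rate: float = 0.0,
    train_fraction: float = 0.5,
) -> dict:
    """Generate a synthetic corpus, train the pattern miner and the type
    classifier on one half, and evaluate on the other half.

    Returns end-to-end exact-match P/R/F1 (full pipeline on raw text), the
    gold-span normalization accuracy under rule-only and rule+pattern
    normalization, and the classifier's holdout macro metrics.
    """
    from . import anchor_resolver, normalizer, pattern_miner, synth_corpus
    from .type_classifier import ClassifierConfig, fit, predict
    from .type_features import LexiconTagger, build_vector

    cfg = synth_corpus.GenConfig(
        n_docs=n_docs,
        seed=seed,
        typo_rate=typo_rate,
        planted_pattern_rate=planted_pattern_rate,
    )
    docs = synth_corpus.generate(cfg)
    n_train = int(round(len(docs) * train_fraction))
    train, test = docs[:n_train], docs[n_train:]

    tagger = LexiconTagger()
    train_vectors = [build_vector(d, tx, tagger) for d in train for tx in d.timexes]
    model = fit(train_vectors, ClassifierConfig(seed=seed))

    miner_cfg = pattern_miner.MinerConfig()
    norm_patterns = pattern_miner.learn(
        train, miner_cfg, pattern_miner.PatternPurpose.NORM_ANCHOR_EQUALS
    )
    lexicons = anchor_resolver.default_lexicons()

    # classifier holdout metrics on the test half
    test_gold, test_pred = [], []
    for d in test:
        for tx in d.timexes:
            test_gold.append(tx.ttype.value)
            test_pred.append(predict(model, build_vector(d, tx, tagger)).value)
    mp, mr, mf, per_class = macro_metrics(test_gold, test_pred)

    # full pipeline on raw text
    pred_docs = [
        normalizer.annotate(d.text, model=model, patterns=norm_patterns,
                            lexicons=lexicons, doc_id=d.doc_id)
        for d in test
    ]
    prf = normalization_prf(test, pred_docs)

    # gold-span normalization accuracy, rule only vs rule + pattern
    acc = {}
    for label, patterns in (("rule", []), ("rule+pattern", norm_patterns)):
        normed = [
            normalizer.normalize_document(d, model=model, patterns=patterns,
                                          lexicons=lexicons)
            for d in test
        ]
        acc[label] = normalization_accuracy(test, normed).accuracy
    return {
        "classifier": {"MP": mp, "MR": mr, "MF": mf, "per_class": per_class},
        "exact_match": prf.as_dict(),
        "accuracy_rule": acc["rule"],
        "accuracy_rule_pattern": acc["rule+pattern"],
        "n_train": len(train),
        "n_test": len(test),
        "n_te_test": len(test_gold),
    }
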