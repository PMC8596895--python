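"""Evaluation: strict span P/R/F1, lenient span F1, and type accuracy.

Three surfaces are reported:

strict
    A predicted span is a true positive only when its (start, end, type)
    triple exists in the gold set — boundaries and type must agree exactly.
lenient span
    Predicted and gold spans are matched one-to-one by greedy maximum token
    overlap, *ignoring type*; a matched pair is a span true positive.  This
    scores boundary detection separately from typing.
type accuracy
    Among the lenient-matched pairs, the fraction whose predicted type
    equals the gold type.

Lenient matching is deliberately one-to-one: unrestricted many-to-many
matching lets one prediction absorb several golds and can push precision
above 1.  Greedy maximum-overlap with ties broken toward the earlier gold
span makes the pairing deterministic.

All corpus-level figures are micro-averaged, and 0/0 ratios are defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .corpus import EventSpan, LabeledSentence, TagSchema, decode_tags

__all__ = [
    "EvalReport",
    "strict_prf",
    "lenient_span_prf",
    "type_accuracy",
    "evaluate",
]

SpanSets = list[list[EventSpan]]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _check_aligned(gold: SpanSets, pred: SpanSets):
    if len(gold) != len(pred):
        raise ValueError(
            f"gold has {len(gold)} sentences but pred has {len(pred)}"
        )


def strict_prf(gold: SpanSets, pred: SpanSets) -> tuple[float, float, float]:
    """Micro-averaged precision/recall/F1 under exact-match span scoring."""
    _check_aligned(gold, pred)
    tp = fp = fn = 0
    for g_set, p_set in zip(gold, pred):
        g = set(g_set)
        p = set(p_set)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    return _prf(tp, fp, fn)


def match_spans(gold: list[EventSpan], pred: list[EventSpan]
                ) -> list[tuple[EventSpan, EventSpan]]:
    """One-to-one greedy maximum-overlap matching, type ignored.

    Candidate (gold, pred) pairs are ranked by overlap length (descending),
    then by gold start, then pred start; each span participates in at most
    one pair.
    """
    candidates = []
    for gi, g in enumerate(sorted(gold)):
        for pi, p in enumerate(sorted(pred)):
            ov = g.overlap(p)
            if ov > 0:
                candidates.append((-ov, g.start, g.end, p.start, p.end, gi, pi, g, p))
    candidates.sort(key=lambda c: c[:5])
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for *_, gi, pi, g, p in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((g, p))
    return pairs


def lenient_span_prf(gold: SpanSets, pred: SpanSets
                     ) -> tuple[float, float, float, list[tuple[EventSpan, EventSpan]]]:
    """Overlap-based span P/R/F1 plus the matched pairs (for type accuracy)."""
    _check_aligned(gold, pred)
    tp = 0
    n_gold = n_pred = 0
    all_pairs: list[tuple[EventSpan, EventSpan]] = []
    for g_set, p_set in zip(gold, pred):
        pairs = match_spans(g_set, p_set)
        tp += len(pairs)
        n_gold += len(g_set)
        n_pred += len(p_set)
        all_pairs.extend(pairs)
    p, r, f = _prf(tp, n_pred - tp, n_gold - tp)
    return p, r, f, all_pairs


def type_accuracy(pairs: list[tuple[EventSpan, EventSpan]]) -> float:
    """Fraction of lenient-matched pairs whose event types agree."""
    if not pairs:
        warnings.warn("type accuracy undefined: no span-matched pairs; "
                      "reporting 0", stacklevel=2)
        return 0.0
    return sum(g.type == p.type for g, p in pairs) / len(pairs)


@dataclass
class EvalReport:
    strict_precision: float
    strict_recall: float
    strict_f1: float
    lenient_precision: float
    lenient_recall: float
    lenient_f1: float
    type_accuracy: float
    per_type_f1: dict[str, float] = field(default_factory=dict)
    n_gold_spans: int = 0
    n_pred_spans: int = 0

    def as_dict(self) -> dict:
        return {
            "strict": {"precision": self.strict_precision,
                       "recall": self.strict_recall,
                       "f1": self.strict_f1},
            "lenient_span": {"precision": self.lenient_precision,
                             "recall": self.lenient_recall,
                             "f1": self.lenient_f1},
            "type_accuracy": self.type_accuracy,
            "per_type_f1": self.per_type_f1,
            "n_gold_spans": self.n_gold_spans,
            "n_pred_spans": self.n_pred_spans,
        }


def evaluate(gold: list[LabeledSentence], pred: list[LabeledSentence],
             schema: TagSchema | None = None,
             decode_mode: str = "forgiving") -> EvalReport:
    """Score predicted sentences against gold on all three surfaces.

    Predictions are decoded forgivingly by default so that ill-formed BIOES
    output from an untrained model still yields spans; gold is decoded
    strictly (it must be schema-valid).
    """
    schema = schema or TagSchema()
    if len(gold) != len(pred):
        raise ValueError("gold and pred corpora differ in length")
    g_sets = [decode_tags(s.tags, mode="strict", schema=schema) for s in gold]
    p_sets = [decode_tags(s.tags, mode=decode_mode, schema=schema) for s in pred]
    sp, sr, sf = strict_prf(g_sets, p_sets)
    lp, lr, lf, pairs = lenient_span_prf(g_sets, p_sets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc = type_accuracy(pairs)
    per_type: dict[str, float] = {}
    for t in schema.types:
        g_t = [[s for s in g if s.type == t] for g in g_sets]
        p_t = [[s for s in p if s.type == t] for p in p_sets]
        per_type[t] = strict_prf(g_t, p_t)[2]
    return EvalReport(
        strict_precision=sp, strict_recall=sr, strict_f1=sf,
        lenient_precision=lp, lenient_recall=lr, lenient_f1=lf,
        type_accuracy=acc, per_type_f1=per_type,
        n_gold_spans=sum(len(g) for g in g_sets),
        n_pred_spans=sum(len(p) for p in p_sets),
    )
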