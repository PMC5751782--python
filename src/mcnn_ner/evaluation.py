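"""Mention-level exact-span evaluation and label-sequence diagnostics.

The metric is the balanced F-score F = 2PR / (P + R) over exact
(doc id, start, end) span matches, micro-averaged over the corpus — the
standard protocol for disease NER shared tasks.  A predicted mention counts
as a true positive only when some gold mention has the identical span;
matching is one-to-one and duplicated predictions collapse before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .corpus_io import LabeledSentence, Mention

__all__ = ["PRF", "mention_prf", "illegal_rate", "is_legal", "balanced_f", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding as used in printed result tables (86.675 -> 86.68)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f": self.f,
        }


def balanced_f(precision: float, recall: float) -> float:
    """F = 2PR / (P + R); 0 when both are 0.  Scale-agnostic (fractions or
    percentages in, same scale out)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mention_prf(pred: list[Mention], gold: list[Mention]) -> PRF:
    """Exact-span micro-averaged precision/recall/F.

    Order-invariant and duplication-invariant: mentions reduce to their
    (doc_id, start, end) span sets before counting.
    """
    pred_spans = {m.span for m in pred}
    gold_spans = {m.span for m in gold}
    tp = len(pred_spans & gold_spans)
    return PRF(tp=tp, fp=len(pred_spans) - tp, fn=len(gold_spans) - tp)


def is_legal(labels: list[str]) -> bool:
    """True iff no I is preceded by anything but B/I (default legality rule)."""
    prev = "O"
    for lab in labels:
        if lab == "I" and prev not in ("B", "I"):
            return False
        prev = lab
    return True


def illegal_rate(labelled: list[LabeledSentence] | list[list[str]]) -> float:
    """Fraction of sentences whose raw label sequence is structurally illegal."""
    if not labelled:
        return 0.0
    seqs = [ls.labels if isinstance(ls, LabeledSentence) else ls for ls in labelled]
    return sum(not is_legal(s) for s in seqs) / len(seqs)
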