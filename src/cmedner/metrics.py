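"""Entity-level evaluation.

A predicted mention counts as a true positive only when its type, start and
end all match a gold mention exactly (strict CoNLL-style matching).
Precision, recall and F1 are reported per entity type and pooled (micro),
as percentages; a metric whose denominator is zero is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import LabeledSequence, TagScheme, tags_to_entities

__all__ = ["TypeMetrics", "EvalReport", "entity_prf", "imbalance_report"]


@dataclass(frozen=True)
class TypeMetrics:
    """Precision/recall/F1 (percent) with raw counts for one type or pooled."""

    precision: float
    recall: float
    f1: float
    support: int  # gold mention count
    predicted: int  # predicted mention count
    tp: int


def _prf(tp: int, n_pred: int, n_gold: int) -> TypeMetrics:
    p = 100.0 * tp / n_pred if n_pred else 0.0
    r = 100.0 * tp / n_gold if n_gold else 0.0
    f = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
    return TypeMetrics(p, r, f, n_gold, n_pred, tp)


@dataclass
class EvalReport:
    """Per-type and micro entity-level metrics."""

    per_type: dict[str, TypeMetrics]
    micro: TypeMetrics

    def to_dict(self, ndigits: int = 2) -> dict:
        def row(m: TypeMetrics) -> dict:
            return {
                "precision": round(m.precision, ndigits),
                "recall": round(m.recall, ndigits),
                "f1": round(m.f1, ndigits),
                "support": m.support,
                "predicted": m.predicted,
            }

        return {
            "per_type": {t: row(m) for t, m in self.per_type.items()},
            "micro": row(self.micro),
        }

    def to_text(self, sep: str = "\t", ndigits: int = 2) -> str:
        lines = [sep.join(["type", "precision", "recall", "f1", "support", "predicted"])]
        for name, m in list(self.per_type.items()) + [("micro", self.micro)]:
            lines.append(
                sep.join(
                    [
                        name,
                        f"{m.precision:.{ndigits}f}",
                        f"{m.recall:.{ndigits}f}",
                        f"{m.f1:.{ndigits}f}",
                        str(m.support),
                        str(m.predicted),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def entity_prf(
    gold: Sequence[LabeledSequence],
    pred: Sequence[Sequence[str]],
    scheme: TagScheme | None = None,
) -> EvalReport:
    """Strict entity-level precision/recall/F1 of predicted tag sequences.

    ``pred`` holds one tag list per gold sentence, aligned in order and
    length.  Types are reported in scheme order when a scheme is given,
    otherwise in sorted order of the types observed.
    """
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold sentences but {len(pred)} predictions")
    gold_spans: dict[str, set] = {}
    pred_spans: dict[str, set] = {}
    for idx, (gseq, ptags) in enumerate(zip(gold, pred)):
        ptags = list(ptags)
        if len(ptags) != len(gseq):
            raise ValueError(
                f"sentence {idx}: {len(gseq)} characters but {len(ptags)} predicted tags"
            )
        for m in tags_to_entities(gseq):
            gold_spans.setdefault(m.type, set()).add((idx, m.start, m.end))
        for m in tags_to_entities(LabeledSequence(gseq.chars, ptags)):
            pred_spans.setdefault(m.type, set()).add((idx, m.start, m.end))

    if scheme is not None:
        types = list(scheme.entity_types)
    else:
        types = sorted(set(gold_spans) | set(pred_spans))
    per_type = {}
    tp_total = gold_total = pred_total = 0
    for t in types:
        g = gold_spans.get(t, set())
        p = pred_spans.get(t, set())
        tp = len(g & p)
        per_type[t] = _prf(tp, len(p), len(g))
        tp_total += tp
        gold_total += len(g)
        pred_total += len(p)
    return EvalReport(per_type, _prf(tp_total, pred_total, gold_total))


def imbalance_report(
    report: EvalReport, corpus: Sequence[LabeledSequence]
) -> pd.DataFrame:
    """Join per-type metrics with training-corpus mention counts.

    Returns a table ``(type, train_support, precision, recall, f1)`` sorted
    by training support, descending, for studying how skewed mention counts
    depress recognition of rare entity types.
    """
    counts: dict[str, int] = {t: 0 for t in report.per_type}
    for seq in corpus:
        for m in tags_to_entities(seq):
            counts[m.type] = counts.get(m.type, 0) + 1
    rows = [
        {
            "type": t,
            "train_support": counts.get(t, 0),
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        }
        for t, m in report.per_type.items()
    ]
    df = pd.DataFrame(rows, columns=["type", "train_support", "precision", "recall", "f1"])
    return df.sort_values("train_support", ascending=False, kind="stable").reset_index(
        drop=True
    )
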