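"""Entity-level precision/recall/F1 and per-token confusion matrices.

Scoring follows the conventions of standard sequence-labeling evaluation:
spans are decoded leniently from both gold and predicted tags, and a
predicted span is a true positive iff its class, start and end all match a
gold span.  Micro-averaged metrics pool true/false positives and negatives
over the whole corpus; the confusion matrix is tallied per token at class
level (B-X and I-X both collapse to X) with ``O`` as its own row/column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .labels import LabelScheme, decode_entities


@dataclass(frozen=True)
class ClassMetrics:
    support: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class OverallMetrics:
    support: int
    precision: float
    recall: float
    f1: float
    token_accuracy: float


@dataclass(frozen=True)
class EvalReport:
    """Per-class and micro-averaged entity metrics for one corpus."""

    per_class: dict[str, ClassMetrics]
    overall: OverallMetrics

    def to_json(self) -> dict:
        return {
            "per_class": {
                cls: vars(m).copy() for cls, m in self.per_class.items()
            },
            "overall": vars(self.overall).copy(),
        }

    def render(self) -> str:
        """Aligned text table: support, precision, recall, F1 per class."""
        rows = [f"{'':<10}{'support':>9}{'precision':>11}{'recall':>9}{'f1':>9}"]
        for cls, m in self.per_class.items():
            rows.append(
                f"{cls:<10}{m.support:>9}{m.precision:>11.4f}"
                f"{m.recall:>9.4f}{m.f1:>9.4f}"
            )
        o = self.overall
        rows.append(
            f"{'overall':<10}{o.support:>9}{o.precision:>11.4f}"
            f"{o.recall:>9.4f}{o.f1:>9.4f}   acc={o.token_accuracy:.4f}"
        )
        return "\n".join(rows)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Token-level tallies of gold class vs predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (n_classes, n_classes), gold rows, predicted columns

    @property
    def row_normalized(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    def to_json(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.astype(int).tolist(),
            "row_normalized": self.row_normalized.round(6).tolist(),
        }

    def render(self, normalized: bool = True) -> str:
        data = self.row_normalized if normalized else self.counts
        corner = "gold/pred"
        head = f"{corner:<10}" + "".join(f"{c:>8}" for c in self.classes)
        rows = [head]
        for i, cls in enumerate(self.classes):
            cells = "".join(
                f"{data[i, j]:>8.3f}" if normalized else f"{int(data[i, j]):>8}"
                for j in range(len(self.classes))
            )
            rows.append(f"{cls:<10}{cells}")
        return "\n".join(rows)


def _prf(tp: int, n_pred: int, n_gold: int) -> tuple[float, float, float]:
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_gold if n_gold else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def entity_prf(
    gold: Sequence[Sequence[str]],
    pred: Sequence[Sequence[str]],
    scheme: LabelScheme,
) -> EvalReport:
    """Micro and per-class entity precision/recall/F1 over aligned corpora.

    ``gold`` and ``pred`` are parallel lists of tag sequences.  Classes with
    zero gold *and* zero predicted spans score 0 (with a warning) rather
    than dividing by zero.
    """
    if len(gold) != len(pred):
        raise ValueError(f"corpus size mismatch: {len(gold)} vs {len(pred)}")
    tp = dict.fromkeys(scheme.classes, 0)
    n_gold = dict.fromkeys(scheme.classes, 0)
    n_pred = dict.fromkeys(scheme.classes, 0)
    correct_tokens = 0
    total_tokens = 0
    for i, (g_seq, p_seq) in enumerate(zip(gold, pred)):
        if len(g_seq) != len(p_seq):
            raise ValueError(f"sequence {i}: length mismatch")
        correct_tokens += sum(a == b for a, b in zip(g_seq, p_seq))
        total_tokens += len(g_seq)
        g_spans = set(decode_entities(g_seq, scheme))
        p_spans = set(decode_entities(p_seq, scheme))
        for span in g_spans:
            n_gold[span.cls] += 1
        for span in p_spans:
            n_pred[span.cls] += 1
        for span in g_spans & p_spans:
            tp[span.cls] += 1
    per_class = {}
    for cls in scheme.classes:
        if n_gold[cls] == 0 and n_pred[cls] == 0:
            warnings.warn(
                f"class {cls!r} has no gold or predicted spans; metrics set to 0",
                stacklevel=2,
            )
        p, r, f1 = _prf(tp[cls], n_pred[cls], n_gold[cls])
        per_class[cls] = ClassMetrics(n_gold[cls], p, r, f1)
    total_tp = sum(tp.values())
    p, r, f1 = _prf(total_tp, sum(n_pred.values()), sum(n_gold.values()))
    overall = OverallMetrics(
        support=sum(n_gold.values()),
        precision=p,
        recall=r,
        f1=f1,
        token_accuracy=correct_tokens / total_tokens if total_tokens else 0.0,
    )
    return EvalReport(per_class, overall)


def token_confusion(
    gold: Sequence[Sequence[str]],
    pred: Sequence[Sequence[str]],
    scheme: LabelScheme,
    tag_level: bool = False,
) -> ConfusionMatrix:
    """Per-token confusion matrix, class-level by default (``tag_level=True``
    keeps the B-/I- prefixes as separate rows/columns)."""
    if len(gold) != len(pred):
        raise ValueError(f"corpus size mismatch: {len(gold)} vs {len(pred)}")
    if tag_level:
        axis = scheme.tags
        key = {t: i for i, t in enumerate(axis)}

        def idx(tag: str) -> int:
            return key[tag]

    else:
        axis = ("O", *scheme.classes)
        key = {c: i for i, c in enumerate(axis)}

        def idx(tag: str) -> int:
            return key["O" if tag == "O" else tag[2:]]

    counts = np.zeros((len(axis), len(axis)), dtype=np.int64)
    for i, (g_seq, p_seq) in enumerate(zip(gold, pred)):
        if len(g_seq) != len(p_seq):
            raise ValueError(f"sequence {i}: length mismatch")
        for g, p in zip(g_seq, p_seq):
            scheme._check(g, None)
            scheme._check(p, None)
            counts[idx(g), idx(p)] += 1
    return ConfusionMatrix(tuple(axis), counts)
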