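"""End-to-end evaluation harness plus detection metrics.

Predicted records are scored against ground truth three ways: label
writing-class accuracy, field-presence accuracy (does the pipeline agree
on which fields carry text), and per-field text similarity under the
Gestalt (Ratcliff/Obershelp) statistic after aggressive normalization
(non-ASCII and punctuation removed, case-insensitive). Only (sheet,
field) pairs with text on at least one side enter the similarity pool; a
field present on exactly one side scores zero.

Detection quality is measured per class as precision/recall/f1 at an IoU
threshold (greedy one-to-one matching by confidence), with VOC-style
average precision as a secondary utility.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field as dc_field
from statistics import fmean, median
from typing import Optional, Sequence

from .core import BoundingBox, FieldClass, LabelClass, SpecimenRecord, iou
from .taxonmatch import gestalt_similarity

_PUNCT = set(string.punctuation)


def normalize_for_eval(text: str) -> str:
    """Strip every non-ASCII character and punctuation mark, lower-case,
    collapse internal whitespace, strip the edges."""
    kept = []
    for ch in text:
        if ord(ch) > 127 or ch in _PUNCT:
            continue
        kept.append(ch.lower())
    return " ".join("".join(kept).split())


def field_similarity(
    predicted: Optional[str], truth: Optional[str]
) -> Optional[float]:
    """Similarity for one (sheet, field) pair; None means excluded.

    Both sides absent (None or blank) -> excluded from aggregation.
    Exactly one side present -> 0.0. Both present -> Gestalt similarity of
    the normalized texts.
    """
    p = predicted if predicted and predicted.strip() else None
    t = truth if truth and truth.strip() else None
    if p is None and t is None:
        return None
    if p is None or t is None:
        return 0.0
    return gestalt_similarity(normalize_for_eval(p), normalize_for_eval(t))


@dataclass
class GroundTruthRecord:
    """True label class and per-field text for one sheet; a missing key
    means the field is not on the label."""

    sheet_id: str
    label_class: LabelClass
    fields: dict[FieldClass, str] = dc_field(default_factory=dict)


@dataclass
class EvalSummary:
    """Aggregate results, all on the 0–100 percent scale."""

    n_sheets: int
    label_classification_accuracy: float
    field_present_accuracy: float
    similarity_median: float
    similarity_mean: float
    per_field_similarities: dict[FieldClass, list[float]]

    def format_table(self) -> str:
        rows = [
            ("Sheets", f"{self.n_sheets}"),
            (
                "Label classification accuracy",
                f"{self.label_classification_accuracy:.1f}",
            ),
            ("Field present accuracy", f"{self.field_present_accuracy:.1f}"),
            ("Text similarity median", f"{self.similarity_median:.1f}"),
            ("Text similarity mean", f"{self.similarity_mean:.1f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def summarize(
    predictions: Sequence[SpecimenRecord],
    truths: Sequence[GroundTruthRecord],
) -> EvalSummary:
    """Score a batch of predictions against ground truth (1:1 by sheet_id).

    Raises listing the orphans when the two sides do not cover the same
    sheets.
    """
    pred_by_id = {r.sheet_id: r for r in predictions}
    truth_by_id = {t.sheet_id: t for t in truths}
    orphans = set(pred_by_id) ^ set(truth_by_id)
    if orphans:
        raise ValueError(f"unmatched sheet_ids: {sorted(orphans)}")

    label_hits = 0
    presence_hits = 0
    presence_total = 0
    sims: list[float] = []
    per_field: dict[FieldClass, list[float]] = {fc: [] for fc in FieldClass}

    for sheet_id, truth in truth_by_id.items():
        pred = pred_by_id[sheet_id]
        if pred.label_class is truth.label_class:
            label_hits += 1
        for fc in FieldClass:
            p_text = pred.field_text(fc)
            t_text = truth.fields.get(fc)
            sim = field_similarity(p_text, t_text)
            if sim is None:
                continue
            presence_total += 1
            p_present = bool(p_text and p_text.strip())
            t_present = bool(t_text and t_text.strip())
            if p_present == t_present:
                presence_hits += 1
            sims.append(sim)
            per_field[fc].append(sim)

    n = len(truth_by_id)
    return EvalSummary(
        n_sheets=n,
        label_classification_accuracy=100.0 * label_hits / n if n else 0.0,
        field_present_accuracy=(
            100.0 * presence_hits / presence_total if presence_total else 100.0
        ),
        similarity_median=100.0 * median(sims) if sims else 100.0,
        similarity_mean=100.0 * fmean(sims) if sims else 100.0,
        per_field_similarities={fc: v for fc, v in per_field.items() if v},
    )


Detection = tuple[str, BoundingBox, float]  # (class name, box, confidence)
Truth = tuple[str, BoundingBox]


def _match_class(
    preds: list[Detection], truths: list[Truth], iou_threshold: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching by descending confidence; returns
    (true positives, n predictions, n truths)."""
    used = [False] * len(truths)
    tp = 0
    for _, box, _ in sorted(preds, key=lambda d: -d[2]):
        best_j, best_iou = -1, iou_threshold
        for j, (_, tbox) in enumerate(truths):
            if used[j]:
                continue
            v = iou(box, tbox)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            used[best_j] = True
            tp += 1
    return tp, len(preds), len(truths)


def detection_f1(
    predictions: Sequence[Detection],
    truths: Sequence[Truth],
    iou_threshold: float = 0.5,
) -> dict[str, tuple[float, float, float]]:
    """Per-class (precision, recall, f1) at an IoU threshold.

    A prediction matches an unmatched truth box of the same class with IoU
    at or above the threshold; matching is greedy by descending
    confidence. f1 is 0 when precision + recall is 0.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")
    classes = sorted({c for c, _, _ in predictions} | {c for c, _ in truths})
    out = {}
    for cls in classes:
        tp, n_pred, n_truth = _match_class(
            [p for p in predictions if p[0] == cls],
            [t for t in truths if t[0] == cls],
            iou_threshold,
        )
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_truth if n_truth else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[cls] = (precision, recall, f1)
    return out


def average_precision(
    predictions: Sequence[Detection],
    truths: Sequence[Truth],
    iou_threshold: float = 0.5,
) -> dict[str, float]:
    """VOC-style per-class average precision at an IoU threshold
    (precision envelope integrated over recall). Secondary utility; f1 at
    IoU 0.5 is the primary detection metric surface."""
    classes = sorted({c for c, _, _ in predictions} | {c for c, _ in truths})
    out = {}
    for cls in classes:
        preds = sorted((p for p in predictions if p[0] == cls), key=lambda d: -d[2])
        cls_truths = [t for t in truths if t[0] == cls]
        used = [False] * len(cls_truths)
        tps = []
        for _, box, _ in preds:
            best_j, best_iou = -1, iou_threshold
            for j, (_, tbox) in enumerate(cls_truths):
                if used[j]:
                    continue
                v = iou(box, tbox)
                if v >= best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                used[best_j] = True
                tps.append(1)
            else:
                tps.append(0)
        if not cls_truths:
            out[cls] = 0.0
            continue
        ap = 0.0
        cum_tp = 0
        prev_recall = 0.0
        best_prec: list[float] = []
        recalls: list[float] = []
        for i, hit in enumerate(tps, 1):
            cum_tp += hit
            best_prec.append(cum_tp / i)
            recalls.append(cum_tp / len(cls_truths))
        # precision envelope (monotone non-increasing from the right)
        for i in range(len(best_prec) - 2, -1, -1):
            best_prec[i] = max(best_prec[i], best_prec[i + 1])
        for prec, rec in zip(best_prec, recalls):
            ap += (rec - prev_recall) * prec
            prev_recall = rec
        out[cls] = ap
    return out


def mean_average_precision(
    predictions: Sequence[Detection],
    truths: Sequence[Truth],
    iou_threshold: float = 0.5,
) -> float:
    """Mean of per-class AP (mAP50 when iou_threshold is 0.5)."""
    aps = average_precision(predictions, truths, iou_threshold)
    return fmean(aps.values()) if aps else 0.0
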