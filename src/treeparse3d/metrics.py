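"""Semantic and instance-level segmentation metrics.

Semantic quality is measured by mIoU over the two classes (background,
crown). Instance quality uses point-set IoU matching at a threshold tau:
each predicted crown is greedily matched (descending IoU, one-to-one) to a
ground-truth crown; a matched pair with IoU >= tau is a true positive,
unmatched predictions are false positives and unmatched ground-truth
instances false negatives. From these, Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F = 2PR/(P+R), and AP is the area under the stepwise
precision-recall curve (all-point rectangle integration) with predictions
ranked by confidence. Instance ID 0 always means background/unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SemanticConfusion", "InstanceMatchResult", "semantic_miou",
    "match_instances", "f_score", "average_precision",
]


@dataclass
class SemanticConfusion:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_classes: int = 2


@dataclass
class InstanceMatchResult:
    tau: float
    pairs: list[tuple[int, int, float]]     # (pred_id, gt_id, IoU)
    tp: int
    fp: int
    fn: int
    pr_curve: tuple[np.ndarray, np.ndarray] | None = field(default=None)
    ap: float | None = None

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fscore(self) -> float:
        return f_score(self.precision, self.recall)


def semantic_miou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-class IoU = TP_i / (TP_i + FP_i + FN_i) over classes {0,1}.

    A class absent from both prediction and ground truth is excluded from
    the mean (with a warning).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError("pred and gt must have equal length")
    ious = []
    for c in (0, 1):
        tp = int(np.sum((pred == c) & (gt == c)))
        fp = int(np.sum((pred == c) & (gt != c)))
        fn = int(np.sum((pred != c) & (gt == c)))
        if tp + fp + fn == 0:
            log.warning("class %d absent from pred and gt; excluded from mIoU", c)
            continue
        ious.append(tp / (tp + fp + fn))
    return float(np.mean(ious)) if ious else 0.0


def _instance_masks(labels: np.ndarray) -> dict[int, np.ndarray]:
    labels = np.asarray(labels)
    return {int(i): labels == i for i in np.unique(labels) if i > 0}


def _iou_table(pred_masks: dict, gt_masks: dict) -> dict[tuple[int, int], float]:
    out = {}
    for pi, pm in pred_masks.items():
        ps = pm.sum()
        for gi, gm in gt_masks.items():
            inter = int(np.sum(pm & gm))
            if inter:
                out[(pi, gi)] = inter / (ps + gm.sum() - inter)
    return out


def match_instances(pred: np.ndarray, gt: np.ndarray,
                    tau: float = 0.5) -> InstanceMatchResult:
    """Greedy one-to-one matching in descending IoU; IoU >= tau counts TP."""
    pred_masks = _instance_masks(pred)
    gt_masks = _instance_masks(gt)
    table = _iou_table(pred_masks, gt_masks)
    cands = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for (pi, gi), iou in cands:
        if iou < tau or pi in used_p or gi in used_g:
            continue
        pairs.append((pi, gi, iou))
        used_p.add(pi)
        used_g.add(gi)
    tp = len(pairs)
    return InstanceMatchResult(tau=tau, pairs=pairs, tp=tp,
                               fp=len(pred_masks) - tp,
                               fn=len(gt_masks) - tp)


def f_score(pre: float, rec: float) -> float:
    """Harmonic mean 2*Pre*Rec/(Pre+Rec); defined as 0 when both are 0."""
    return 2.0 * pre * rec / (pre + rec) if pre + rec > 0 else 0.0


def average_precision(pred: np.ndarray, confidences: dict[int, float],
                      gt: np.ndarray, tau: float = 0.5) -> InstanceMatchResult:
    """AP at IoU tau with predictions ranked by descending confidence.

    Each prediction, in confidence order, is matched to the best still-free
    ground-truth instance with IoU >= tau; cumulative precision/recall give
    the stepwise p(r) curve and AP = sum over TP steps of
    (r_i - r_{i-1}) * p_i (all-point rectangle integration).
    """
    pred_masks = _instance_masks(pred)
    gt_masks = _instance_masks(gt)
    n_gt = len(gt_masks)
    result = match_instances(pred, gt, tau)
    if not pred_masks or n_gt == 0:
        result.ap = 0.0
        result.pr_curve = (np.array([]), np.array([]))
        return result
    order = sorted(pred_masks, key=lambda pi: (-confidences.get(pi, 0.0), pi))
    table = _iou_table(pred_masks, gt_masks)
    free = set(gt_masks)
    hits = []
    for pi in order:
        best_gi, best_iou = None, tau
        for gi in free:
            iou = table.get((pi, gi), 0.0)
            if iou >= best_iou:
                best_gi, best_iou = gi, iou
        if best_gi is not None:
            free.discard(best_gi)
            hits.append(1)
        else:
            hits.append(0)
    hits = np.array(hits)
    cum_tp = np.cumsum(hits)
    prec = cum_tp / np.arange(1, len(hits) + 1)
    rec = cum_tp / n_gt
    ap = 0.0
    prev_r = 0.0
    for p, r, h in zip(prec, rec, hits):
        if h:
            ap += (r - prev_r) * p
            prev_r = r
    result.pr_curve = (rec, prec)
    result.ap = float(ap)
    return result
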