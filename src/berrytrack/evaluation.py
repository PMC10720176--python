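"""Accuracy metrics for detection, segmentation and tracking.

Detection is scored by matching predicted to reference ellipses one to
one (greedy, by descending IoU, with IoU > 0.5 required), yielding
TP/FP/FN counts and the derived precision, recall and F1.  Segmented
areas are compared with bias, RMSE, MAPE and R^2.  Tracking is scored
by the coverage T_c (share of observations that received a label) and
the precision T_p (share of labels whose observations all designate
the same physical berry), computed exhaustively against simulator
ground truth identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from berrytrack.geometry import Ellipse, ellipse_iou

__all__ = [
    "ConfusionCounts",
    "TrackingScore",
    "match_pairs",
    "match_instances",
    "prf",
    "area_metrics",
    "tracking_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int


@dataclass(frozen=True)
class TrackingScore:
    T_c: float  # % of observations labelled
    T_p: float  # % of labels pointing to one berry over time


def match_pairs(pred: list[Ellipse], truth: list[Ellipse],
                iou_min: float = 0.5) -> list[tuple[int, int]]:
    """One-to-one greedy matching by descending IoU.

    Only pairs with IoU strictly above ``iou_min`` are admitted; ties
    are broken by prediction then truth order.  Returns (pred-index,
    truth-index) pairs.
    """
    ious = np.zeros((len(pred), len(truth)))
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            ious[i, j] = ellipse_iou(p, t)
    used_p = np.zeros(len(pred), dtype=bool)
    used_t = np.zeros(len(truth), dtype=bool)
    pairs: list[tuple[int, int]] = []
    if ious.size:
        order = np.argsort(-ious, axis=None, kind="stable")
        for flat in order:
            i, j = divmod(int(flat), len(truth))
            if ious[i, j] <= iou_min:
                break
            if used_p[i] or used_t[j]:
                continue
            used_p[i] = used_t[j] = True
            pairs.append((i, j))
    return pairs


def match_instances(pred: list[Ellipse], truth: list[Ellipse],
                    iou_min: float = 0.5) -> ConfusionCounts:
    """TP/FP/FN counts from the greedy one-to-one IoU matching.

    Matched pairs are true positives; unmatched predictions are false
    positives, unmatched references false negatives.
    """
    tp = len(match_pairs(pred, truth, iou_min))
    return ConfusionCounts(TP=tp, FP=len(pred) - tp, FN=len(truth) - tp)


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1-score as percentages."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("undefined metrics: no predictions or no references")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else \
        2.0 * precision * recall / (precision + recall)
    return precision * 100.0, recall * 100.0, f1 * 100.0


def area_metrics(pred_areas, truth_areas) -> tuple[float, float, float, float]:
    """(bias, RMSE, MAPE %, R^2) of paired area measurements.

    Pairs with zero reference area are skipped.  R^2 is the coefficient
    of determination of predictions against the reference.
    """
    p = np.asarray(pred_areas, dtype=float)
    t = np.asarray(truth_areas, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("need >= 2 paired areas")
    keep = t != 0
    p, t = p[keep], t[keep]
    err = p - t
    bias = float(err.mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    mape = float(np.mean(np.abs(err) / t) * 100.0)
    ss_res = float((err ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return bias, rmse, mape, r2


def tracking_score(labels_by_frame: dict[int, np.ndarray],
                   true_ids_by_frame: dict[int, list[int]]) -> TrackingScore:
    """Coverage and precision of a tracking run against known identities.

    ``labels_by_frame[t]`` holds one tracking label per observation of
    frame ``t`` (-1 = unlabeled); ``true_ids_by_frame[t]`` aligns the
    true berry identity with each observation.
    """
    total = 0
    labelled = 0
    members: dict[int, set[int]] = {}
    for t, labels in labels_by_frame.items():
        ids = true_ids_by_frame[t]
        if len(labels) != len(ids):
            raise ValueError(f"frame {t}: labels/identities length mismatch")
        total += len(labels)
        for lab, tid in zip(labels, ids):
            if lab < 0:
                continue
            labelled += 1
            members.setdefault(int(lab), set()).add(int(tid))
    t_c = 100.0 * labelled / total if total else 0.0
    if members:
        pure = sum(1 for s in members.values() if len(s) == 1)
        t_p = 100.0 * pure / len(members)
    else:
        t_p = 0.0
    return TrackingScore(T_c=t_c, T_p=t_p)
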