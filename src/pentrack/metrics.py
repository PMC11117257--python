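"""Tracking evaluation: HOTA, MOTA, MOTP, IDF1 and identity switches.

All metrics compare a predicted :class:`~pentrack.io.TrajectorySet`
against a ground-truth one.  Per-frame correspondence between boxes is a
one-to-one maximum-IoU bipartite matching at a configurable threshold
(default 0.5).  Every metric is invariant under a global relabeling of
predicted ids.

Conventions:

* MOTA = 1 - (FN + FP + IDSW) / (total gt boxes), as a percentage.  An
  identity switch is counted when the predicted id matched to a
  ground-truth identity differs from the most recent predicted id
  matched to that same identity.
* MOTP is reported in the overlap convention (mean IoU over matches, as
  a percentage); the complementary distance forms (mean ``1 - IoU`` and
  mean center distance in pixels) are returned alongside.
* IDF1 uses the optimal global bipartite assignment between gt and
  predicted identities maximizing IDTP.
* HOTA averages, over localization thresholds alpha in {0.05, ..., 0.95},
  sqrt(DetA * AssA) computed from per-TP association accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Bbox, TrajectorySet

__all__ = [
    "MetricsReport",
    "iou",
    "iou_matrix",
    "frame_match",
    "mota",
    "motp",
    "idf1",
    "hota",
    "idsw_count",
    "evaluate",
]

HOTA_ALPHAS = np.arange(0.05, 1.0, 0.05)


def iou(a: Bbox, b: Bbox) -> float:
    """Intersection-over-union of two ``(left, top, w, h)`` boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    return inter / (aw * ah + bw * bh - inter)


def iou_matrix(boxes_a: Sequence[Bbox], boxes_b: Sequence[Bbox]) -> np.ndarray:
    A = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    B = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    if len(A) == 0 or len(B) == 0:
        return np.zeros((len(A), len(B)))
    ax1, ay1 = A[:, 0], A[:, 1]
    ax2, ay2 = A[:, 0] + A[:, 2], A[:, 1] + A[:, 3]
    bx1, by1 = B[:, 0], B[:, 1]
    bx2, by2 = B[:, 0] + B[:, 2], B[:, 1] + B[:, 3]
    ix = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0, None)
    iy = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0, None)
    inter = ix * iy
    union = (A[:, 2] * A[:, 3])[:, None] + B[:, 2] * B[:, 3] - inter
    return np.where(inter > 0, inter / union, 0.0)


def frame_match(
    gt_boxes: Dict[int, Bbox], pred_boxes: Dict[int, Bbox], iou_threshold: float = 0.5
) -> List[Tuple[int, int, float]]:
    """One-to-one matching of one frame's boxes maximizing total IoU.

    Returns ``(gt_id, pred_id, iou)`` triples; only pairs with IoU >=
    threshold participate.
    """
    gids, pids = sorted(gt_boxes), sorted(pred_boxes)
    M = iou_matrix([gt_boxes[g] for g in gids], [pred_boxes[p] for p in pids])
    eligible = M >= iou_threshold
    if not eligible.any():
        return []
    # maximize IoU over eligible pairs; ineligible pairs get 0 benefit and
    # are filtered after the assignment
    benefit = np.where(eligible, M, 0.0)
    rows, cols = linear_sum_assignment(-benefit)
    return [
        (gids[r], pids[c], float(M[r, c])) for r, c in zip(rows, cols) if eligible[r, c]
    ]


@dataclass
class MetricsReport:
    """One evaluation of a (ground truth, prediction) pair."""

    hota: float
    mota: float
    motp: float
    idf1: float
    idsw: int
    tp: int
    fn: int
    fp: int
    idtp: int
    idfp: int
    idfn: int
    motp_distance: float  # mean (1 - IoU) over matches
    motp_center_px: float  # mean center distance over matches, pixels

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _frames_union(gt: TrajectorySet, pred: TrajectorySet) -> List[int]:
    lo_g, hi_g = gt.frame_range
    lo_p, hi_p = pred.frame_range
    lo = min(lo_g, lo_p) if len(pred) else lo_g
    hi = max(hi_g, hi_p) if len(pred) else hi_g
    return list(range(lo, hi + 1))


def _clear_counts(gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float):
    """Shared per-frame sweep: TP/FN/FP counts, IDSW, and match IoUs."""
    if len(gt) == 0:
        raise ValueError("empty ground truth: metrics undefined")
    tp = fn = fp = idsw = 0
    last_pred_of: Dict[int, int] = {}
    ious: List[float] = []
    center_d: List[float] = []
    for frame in _frames_union(gt, pred):
        g = gt.boxes_in_frame(frame)
        p = pred.boxes_in_frame(frame)
        matches = frame_match(g, p, iou_threshold)
        tp += len(matches)
        fn += len(g) - len(matches)
        fp += len(p) - len(matches)
        for gid, pid, ov in matches:
            if gid in last_pred_of and last_pred_of[gid] != pid:
                idsw += 1
            last_pred_of[gid] = pid
            ious.append(ov)
            gb, pb = g[gid], p[pid]
            gc = (gb[0] + gb[2] / 2, gb[1] + gb[3] / 2)
            pc = (pb[0] + pb[2] / 2, pb[1] + pb[3] / 2)
            center_d.append(float(np.hypot(gc[0] - pc[0], gc[1] - pc[1])))
    return tp, fn, fp, idsw, ious, center_d


def mota(gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float = 0.5):
    """MOTA (%) plus the counts (TP, FN, FP, IDSW) behind it."""
    tp, fn, fp, idsw, _, _ = _clear_counts(gt, pred, iou_threshold)
    total_gt = gt.n_boxes()
    value = (1.0 - (fn + fp + idsw) / total_gt) * 100.0
    return value, {"tp": tp, "fn": fn, "fp": fp, "idsw": idsw, "gt": total_gt}


def idsw_count(gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float = 0.5) -> int:
    """Number of identity switches over the whole sequence."""
    return _clear_counts(gt, pred, iou_threshold)[3]


def motp(gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float = 0.5):
    """MOTP in the overlap convention (mean match IoU, %); also returns the
    distance forms (mean 1-IoU and mean center distance in px)."""
    _, _, _, _, ious, center_d = _clear_counts(gt, pred, iou_threshold)
    if not ious:
        raise ValueError("no matches: MOTP undefined")
    mean_iou = float(np.mean(ious))
    return mean_iou * 100.0, {
        "distance": 1.0 - mean_iou,
        "center_px": float(np.mean(center_d)),
        "n_matches": len(ious),
    }


def idf1(gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float = 0.5):
    """IDF1 (%) with its (IDTP, IDFP, IDFN) decomposition.

    Identity true positives come from a global bipartite assignment of
    gt ids to predicted ids maximizing the number of frames in which the
    paired boxes overlap at the threshold.
    """
    if len(gt) == 0:
        raise ValueError("empty ground truth: IDF1 undefined")
    gids, pids = gt.ids, pred.ids
    overlap = np.zeros((len(gids), len(pids)), dtype=int)
    for frame in _frames_union(gt, pred):
        g = gt.boxes_in_frame(frame)
        p = pred.boxes_in_frame(frame)
        if not g or not p:
            continue
        gl = [i for i in gids if i in g]
        pl = [j for j in pids if j in p]
        M = iou_matrix([g[i] for i in gl], [p[j] for j in pl]) >= iou_threshold
        for a, gid in enumerate(gl):
            for b, pid in enumerate(pl):
                if M[a, b]:
                    overlap[gids.index(gid), pids.index(pid)] += 1
    idtp = 0
    if len(pids):
        rows, cols = linear_sum_assignment(-overlap)
        idtp = int(overlap[rows, cols].sum())
    n_gt, n_pred = gt.n_boxes(), pred.n_boxes()
    idfn = n_gt - idtp
    idfp = n_pred - idtp
    value = 100.0 * 2 * idtp / (2 * idtp + idfp + idfn) if (2 * idtp + idfp + idfn) else 0.0
    return value, {"idtp": idtp, "idfp": idfp, "idfn": idfn}


def hota(
    gt: TrajectorySet,
    pred: TrajectorySet,
    alphas: Sequence[float] = HOTA_ALPHAS,
) -> float:
    """HOTA (%): mean over alpha of sqrt(sum_c A(c) / (TP + FN + FP)).

    For each localization threshold alpha, frames are matched at
    IoU >= alpha; each TP ``c`` pairing gt id ``g`` with pred id ``p``
    contributes the association accuracy
    ``A(c) = TPA / (TPA + FNA + FPA)`` where TPA counts matches pairing
    ``g`` with ``p`` anywhere in the sequence, FNA the remaining gt
    boxes of ``g``, FPA the remaining predicted boxes of ``p``.
    """
    if len(gt) == 0:
        raise ValueError("empty ground truth: HOTA undefined")
    frames = _frames_union(gt, pred)
    gt_len = {g: len(gt.trajectory(g)) for g in gt.ids}
    pred_len = {p: len(pred.trajectory(p)) for p in pred.ids}
    scores = []
    for alpha in alphas:
        pair_count: Dict[Tuple[int, int], int] = {}
        tp = fn = fp = 0
        all_matches: List[Tuple[int, int]] = []
        for frame in frames:
            g = gt.boxes_in_frame(frame)
            p = pred.boxes_in_frame(frame)
            matches = frame_match(g, p, alpha)
            tp += len(matches)
            fn += len(g) - len(matches)
            fp += len(p) - len(matches)
            for gid, pid, _ in matches:
                pair_count[(gid, pid)] = pair_count.get((gid, pid), 0) + 1
                all_matches.append((gid, pid))
        if tp + fn + fp == 0:
            scores.append(0.0)
            continue
        assoc_sum = 0.0
        for gid, pid in all_matches:
            tpa = pair_count[(gid, pid)]
            fna = gt_len[gid] - tpa
            fpa = pred_len.get(pid, 0) - tpa
            assoc_sum += tpa / (tpa + fna + fpa)
        scores.append(np.sqrt(assoc_sum / (tp + fn + fp)))
    return float(np.mean(scores)) * 100.0


def evaluate(
    gt: TrajectorySet, pred: TrajectorySet, iou_threshold: float = 0.5
) -> MetricsReport:
    """Full evaluation of one (ground truth, prediction) pair."""
    tp, fn, fp, idsw, ious, center_d = _clear_counts(gt, pred, iou_threshold)
    total_gt = gt.n_boxes()
    mota_v = (1.0 - (fn + fp + idsw) / total_gt) * 100.0
    mean_iou = float(np.mean(ious)) if ious else float("nan")
    idf1_v, idc = idf1(gt, pred, iou_threshold)
    hota_v = hota(gt, pred)
    return MetricsReport(
        hota=hota_v,
        mota=mota_v,
        motp=mean_iou * 100.0,
        idf1=idf1_v,
        idsw=idsw,
        tp=tp,
        fn=fn,
        fp=fp,
        idtp=idc["idtp"],
        idfp=idc["idfp"],
        idfn=idc["idfn"],
        motp_distance=1.0 - mean_iou,
        motp_center_px=float(np.mean(center_d)) if center_d else float("nan"),
    )
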