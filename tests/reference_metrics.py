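"""Independent, deliberately naive metric implementations used as oracles.

Everything here is written directly from the metric definitions with
explicit Python loops and (for small instances) exhaustive enumeration —
no code shared with ``pentrack.metrics``.
"""

from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment


def iou_ref(a, b):
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    x1, y1 = max(ax, bx), max(ay, by)
    x2, y2 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    if x2 <= x1 or y2 <= y1:
        return 0.0
    inter = (x2 - x1) * (y2 - y1)
    return inter / (aw * ah + bw * bh - inter)


def exhaustive_frame_match(gt_boxes, pred_boxes, thr):
    """Best one-to-one matching by total IoU via brute-force enumeration."""
    gids, pids = sorted(gt_boxes), sorted(pred_boxes)
    best, best_val = [], -1.0
    k = min(len(gids), len(pids))
    if k == 0:
        return []
    # enumerate which gt ids participate and in which order they take pred ids
    from itertools import combinations

    for g_sub in combinations(range(len(gids)), k):
        for p_perm in permutations(range(len(pids)), k):
            pairs = []
            total = 0.0
            for gi, pi in zip(g_sub, p_perm):
                ov = iou_ref(gt_boxes[gids[gi]], pred_boxes[pids[pi]])
                if ov >= thr:
                    pairs.append((gids[gi], pids[pi], ov))
                    total += ov
            if total > best_val or (total == best_val and len(pairs) > len(best)):
                best, best_val = pairs, total
    # keep only the threshold-passing pairs of the best-total matching
    return best


def per_frame_matches(gt, pred, thr, exhaustive=False):
    lo = min(gt.frame_range[0], pred.frame_range[0] if len(pred) else gt.frame_range[0])
    hi = max(gt.frame_range[1], pred.frame_range[1] if len(pred) else gt.frame_range[1])
    out = {}
    for f in range(lo, hi + 1):
        g = gt.boxes_in_frame(f)
        p = pred.boxes_in_frame(f)
        if exhaustive:
            out[f] = exhaustive_frame_match(g, p, thr)
        else:
            gids, pids = sorted(g), sorted(p)
            M = np.zeros((len(gids), len(pids)))
            for i, gi in enumerate(gids):
                for j, pj in enumerate(pids):
                    M[i, j] = iou_ref(g[gi], p[pj])
            B = np.where(M >= thr, M, 0.0)
            rows, cols = linear_sum_assignment(-B)
            out[f] = [
                (gids[r], pids[c], M[r, c]) for r, c in zip(rows, cols) if M[r, c] >= thr
            ]
    return out


def mota_ref(gt, pred, thr=0.5, exhaustive=False):
    matches = per_frame_matches(gt, pred, thr, exhaustive)
    fn = fp = idsw = 0
    last = {}
    for f in sorted(matches):
        m = matches[f]
        fn += len(gt.boxes_in_frame(f)) - len(m)
        fp += len(pred.boxes_in_frame(f)) - len(m)
        for gid, pid, _ in m:
            if gid in last and last[gid] != pid:
                idsw += 1
            last[gid] = pid
    return (1 - (fn + fp + idsw) / gt.n_boxes()) * 100.0, idsw


def idf1_ref(gt, pred, thr=0.5, exhaustive=False):
    matches = per_frame_matches(gt, pred, thr, exhaustive)
    gids, pids = gt.ids, pred.ids
    cnt = {}
    for f, m in matches.items():
        for gid, pid, _ in m:
            cnt[(gid, pid)] = cnt.get((gid, pid), 0) + 1
    if not pids:
        idtp = 0
    elif len(gids) <= 6 and len(pids) <= 6:
        # exhaustive assignment over id pairings
        idtp = 0
        k = min(len(gids), len(pids))
        from itertools import combinations

        for g_sub in combinations(gids, k):
            for p_perm in permutations(pids, k):
                tot = sum(cnt.get((g, p), 0) for g, p in zip(g_sub, p_perm))
                idtp = max(idtp, tot)
    else:
        M = np.zeros((len(gids), len(pids)))
        for (g, p), c in cnt.items():
            M[gids.index(g), pids.index(p)] = c
        rows, cols = linear_sum_assignment(-M)
        idtp = int(M[rows, cols].sum())
    idfn = gt.n_boxes() - idtp
    idfp = pred.n_boxes() - idtp
    denom = 2 * idtp + idfp + idfn
    return (100.0 * 2 * idtp / denom) if denom else 0.0


def hota_ref(gt, pred, exhaustive=False):
    alphas = np.arange(0.05, 1.0, 0.05)
    gt_len = {g: len(gt.trajectory(g)) for g in gt.ids}
    pr_len = {p: len(pred.trajectory(p)) for p in pred.ids}
    vals = []
    for a in alphas:
        matches = per_frame_matches(gt, pred, a, exhaustive)
        cnt = {}
        flat = []
        tp = fn = fp = 0
        for f, m in matches.items():
            tp += len(m)
            fn += len(gt.boxes_in_frame(f)) - len(m)
            fp += len(pred.boxes_in_frame(f)) - len(m)
            for gid, pid, _ in m:
                cnt[(gid, pid)] = cnt.get((gid, pid), 0) + 1
                flat.append((gid, pid))
        if tp + fn + fp == 0:
            vals.append(0.0)
            continue
        s = 0.0
        for gid, pid in flat:
            tpa = cnt[(gid, pid)]
            s += tpa / (tpa + (gt_len[gid] - tpa) + (pr_len.get(pid, 0) - tpa))
        vals.append(np.sqrt(s / (tp + fn + fp)))
    return float(np.mean(vals)) * 100.0
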