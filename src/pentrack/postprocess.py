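"""Offline trajectory correction: gap interpolation and tracklet linking.

Two optional, appearance-free stages applied after online tracking:

* **Gaussian-smoothed interpolation (GSI)** — per trajectory, each box
  coordinate (center-x, center-y, width, height) is regressed on the
  frame index with a Gaussian process (RBF kernel over time, fitted
  white-noise term).  Missing frames inside gaps up to ``max_gap`` are
  filled from the posterior mean, and observed frames are replaced by it
  (smoothing), so nonlinear motion through a detection gap is
  reconstructed rather than linearly bridged.
* **Tracklet linking (AFLink-style)** — fragmented identities are
  re-joined from spatiotemporal footprints alone.  Each candidate
  (predecessor, successor) pair is summarized by the nearest N = 30
  frames of ``(frame, x, y)`` rows on either side of the gap
  (zero-padded when shorter), temporal-difference features are extracted
  along the time axis, fused with the gap/offset deltas, and a small MLP
  head scores the association confidence in [0, 1]; links are accepted
  by linear assignment subject to spatiotemporal constraints.

Both stages preserve or reduce the set of identities; neither ever
invents a new one.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .io import Bbox, TrajectorySet
from .simulate import Scenario

__all__ = [
    "gsi_smooth",
    "gsi_correct",
    "AFLinkModel",
    "aflink_features",
    "aflink_train",
    "aflink_associate",
]

N_FOOTPRINT = 30  # frames of context per side of a candidate link


# ---------------------------------------------------------------------------
# Gaussian-smoothed interpolation
# ---------------------------------------------------------------------------

_GP_WINDOW = 300   # observations per GP fit; cubic cost caps here
_GP_OVERLAP = 25   # observations of context shared between windows


def gsi_smooth(
    trajectory: Dict[int, Bbox],
    length_scale: float = 10.0,
    max_gap: Optional[int] = None,
) -> Dict[int, Bbox]:
    """Smooth one trajectory and fill its gaps with a Gaussian process.

    ``length_scale`` is the RBF correlation length in frames;
    ``max_gap`` bounds the gap size (in missing frames) that gets
    filled — larger gaps are left open.  Single-point trajectories are
    returned unchanged.  Long trajectories are fitted in overlapping
    windows of a few hundred observations (the RBF correlation length is
    tens of frames, so distant windows are independent anyway), keeping
    the cubic GP cost linear in track length.
    """
    frames = np.array(sorted(trajectory))
    if len(frames) < 2:
        return dict(trajectory)
    if len(frames) > _GP_WINDOW + 2 * _GP_OVERLAP:
        return _gsi_windowed(trajectory, frames, length_scale, max_gap)
    obs = np.array(
        [
            (
                trajectory[f][0] + trajectory[f][2] / 2,
                trajectory[f][1] + trajectory[f][3] / 2,
                trajectory[f][2],
                trajectory[f][3],
            )
            for f in frames
        ]
    )
    # frames to predict: all observed, plus gap interiors up to max_gap
    targets = set(int(f) for f in frames)
    for a, b in zip(frames[:-1], frames[1:]):
        gap = int(b - a - 1)
        if gap > 0 and (max_gap is None or gap <= max_gap):
            targets.update(range(int(a) + 1, int(b)))
    target_frames = np.array(sorted(targets))

    X = frames[:, None].astype(float)
    Xp = target_frames[:, None].astype(float)
    pred = np.empty((len(target_frames), 4))
    for k in range(4):
        kernel = RBF(length_scale=length_scale, length_scale_bounds="fixed") + WhiteKernel(
            noise_level=1e-2, noise_level_bounds=(1e-10, 1e3)
        )
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True)
        with warnings.catch_warnings():
            # noiseless tracks drive the fitted noise to its lower bound
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, obs[:, k])
        pred[:, k] = gp.predict(Xp)
    out: Dict[int, Bbox] = {}
    for i, f in enumerate(target_frames):
        cx, cy, w, h = pred[i]
        w, h = max(w, 1e-3), max(h, 1e-3)
        out[int(f)] = (cx - w / 2, cy - h / 2, w, h)
    return out


def _gsi_windowed(
    trajectory: Dict[int, Bbox],
    frames: np.ndarray,
    length_scale: float,
    max_gap: Optional[int],
) -> Dict[int, Bbox]:
    """Apply gsi_smooth window-by-window and keep each window's interior."""
    n = len(frames)
    step = _GP_WINDOW - 2 * _GP_OVERLAP
    out: Dict[int, Bbox] = {}
    for s in range(0, n, step):
        lo, hi = max(s - _GP_OVERLAP, 0), min(s + step + _GP_OVERLAP, n)
        chunk = {int(f): trajectory[int(f)] for f in frames[lo:hi]}
        smoothed = gsi_smooth(chunk, length_scale=length_scale, max_gap=max_gap)
        own_lo = frames[s]
        # own everything up to (not including) the next window's first frame,
        # so gap fills straddling the boundary are kept exactly once
        own_hi = frames[s + step] - 1 if s + step < n else frames[n - 1]
        for f, bbox in smoothed.items():
            if own_lo <= f <= own_hi:
                out[f] = bbox
    return out


def gsi_correct(
    trajectories: TrajectorySet,
    length_scale: float = 10.0,
    max_gap: Optional[int] = None,
) -> TrajectorySet:
    """Apply :func:`gsi_smooth` to every identity of a trajectory set.

    ``max_gap`` defaults to 3 seconds worth of frames.  Only geometry
    changes; the identity set is preserved.
    """
    if max_gap is None:
        max_gap = int(round(3.0 * trajectories.fps))
    out = TrajectorySet(fps=trajectories.fps)
    for tid in trajectories.ids:
        traj = trajectories.trajectory(tid)
        smoothed = gsi_smooth(traj, length_scale=length_scale, max_gap=max_gap)
        for frame, bbox in smoothed.items():
            conf = trajectories.confidence(tid, frame) if frame in traj else 1.0
            out.add(tid, frame, bbox, conf)
    return out


# ---------------------------------------------------------------------------
# tracklet linking
# ---------------------------------------------------------------------------

def _footprint(traj: Dict[int, Bbox], side: str) -> np.ndarray:
    """N x 3 matrix of (frame, cx, cy): trajectory tail or head, zero-padded."""
    frames = sorted(traj)
    sel = frames[-N_FOOTPRINT:] if side == "tail" else frames[:N_FOOTPRINT]
    rows = np.zeros((N_FOOTPRINT, 3))
    data = np.array(
        [(f, traj[f][0] + traj[f][2] / 2, traj[f][1] + traj[f][3] / 2) for f in sel]
    )
    if side == "tail":  # pad in front so the gap-adjacent rows stay at the end
        rows[N_FOOTPRINT - len(data):] = data
    else:
        rows[: len(data)] = data
    return rows


def aflink_features(
    track_i: Dict[int, Bbox], track_j: Dict[int, Bbox]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatiotemporal footprints and deltas of a candidate link.

    ``track_i`` must end strictly before ``track_j`` starts.  Returns
    ``(tail_footprint, head_footprint, deltas)`` where the footprints
    are N x 3 ``(frame, x, y)`` matrices (N = 30, zero-padded) and
    deltas = (frame gap, dx, dy) across the junction.
    """
    end_i, start_j = max(track_i), min(track_j)
    if end_i >= start_j:
        raise ValueError("tracks overlap in time: not a valid predecessor/successor pair")
    tail = _footprint(track_i, "tail")
    head = _footprint(track_j, "head")
    bi, bj = track_i[end_i], track_j[start_j]
    ci = (bi[0] + bi[2] / 2, bi[1] + bi[3] / 2)
    cj = (bj[0] + bj[2] / 2, bj[1] + bj[3] / 2)
    deltas = np.array([start_j - end_i, cj[0] - ci[0], cj[1] - ci[1]])
    return tail, head, deltas


def _mean_velocity(footprint: np.ndarray) -> np.ndarray:
    """Temporal-difference features of one footprint: mean and sd of the
    per-frame velocity over the non-padded rows."""
    valid = footprint[np.any(footprint != 0, axis=1)]
    if len(valid) < 2:
        return np.zeros(4)
    df = np.diff(valid[:, 0])
    df[df == 0] = 1.0
    v = np.diff(valid[:, 1:], axis=0) / df[:, None]
    return np.concatenate([v.mean(axis=0), v.std(axis=0)])


def _pair_vector(tail: np.ndarray, head: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    gap, dx, dy = deltas
    v_tail = _mean_velocity(tail)
    v_head = _mean_velocity(head)
    # forward extrapolation of the predecessor across the gap vs reality
    resid_fwd = np.array([dx, dy]) - v_tail[:2] * gap
    resid_bwd = np.array([dx, dy]) - v_head[:2] * gap
    return np.concatenate(
        [
            [gap, dx, dy, float(np.hypot(dx, dy))],
            v_tail,
            v_head,
            resid_fwd,
            resid_bwd,
            [float(np.hypot(*resid_fwd)), float(np.hypot(*resid_bwd))],
        ]
    )


@dataclass
class AFLinkModel:
    """Trained link scorer: feature scaler + MLP classifier head.

    ``predict_confidence`` maps a candidate pair to an association
    confidence in [0, 1]; ``heldout_accuracy`` records the accuracy on
    the held-out split of the training pairs.
    """

    scaler: StandardScaler
    classifier: MLPClassifier
    heldout_accuracy: float

    def predict_confidence(
        self, tail: np.ndarray, head: np.ndarray, deltas: np.ndarray
    ) -> float:
        x = self.scaler.transform(_pair_vector(tail, head, deltas)[None, :])
        return float(self.classifier.predict_proba(x)[0, 1])

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str) -> "AFLinkModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain an AFLinkModel")
        return obj


def _cut_pairs(scenario: Scenario, rng: np.random.Generator, pairs_per_id: int):
    """Positive pairs: one trajectory cut at a random frame with a random
    gap; negatives: tail of one identity vs head of another."""
    positives, negatives = [], []
    ids = scenario.gt.ids
    trajs = {tid: scenario.gt.trajectory(tid) for tid in ids}
    for tid in ids:
        frames = sorted(trajs[tid])
        if len(frames) < 80:
            continue
        for _ in range(pairs_per_id):
            cut = int(rng.integers(40, len(frames) - 40))
            gap = int(rng.integers(1, N_FOOTPRINT + 1))
            left = {f: trajs[tid][f] for f in frames[:cut]}
            right = {f: trajs[tid][f] for f in frames[cut + gap :]}
            if not right:
                continue
            positives.append((left, right))
            other = int(rng.choice([o for o in ids if o != tid])) if len(ids) > 1 else None
            if other is not None:
                right_o = {f: trajs[other][f] for f in sorted(trajs[other]) if f >= frames[cut + gap]}
                if right_o:
                    negatives.append((left, right_o))
    return positives, negatives


def aflink_train(
    scenarios: Sequence[Scenario],
    seed: int = 0,
    pairs_per_id: int = 20,
    hidden: Tuple[int, ...] = (32, 16),
) -> AFLinkModel:
    """Train the link scorer on simulator-generated cut pairs.

    For every ground-truth identity, trajectories are cut at random
    frames with random gaps to form positive (same-identity) pairs;
    negatives pair the tail of one identity with the head of another.
    A quarter of the pairs is held out; training is deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    for sc in scenarios:
        pos, neg = _cut_pairs(sc, rng, pairs_per_id)
        for left, right in pos:
            X.append(_pair_vector(*aflink_features(left, right)))
            y.append(1)
        for left, right in neg:
            X.append(_pair_vector(*aflink_features(left, right)))
            y.append(0)
    if len(X) < 8 or len(set(y)) < 2:
        raise ValueError(f"too few training pairs ({len(X)}) — use longer or more scenarios")
    X = np.asarray(X)
    y = np.asarray(y)
    order = rng.permutation(len(X))
    X, y = X[order], y[order]
    n_hold = max(len(X) // 4, 1)
    X_tr, y_tr = X[n_hold:], y[n_hold:]
    X_te, y_te = X[:n_hold], y[:n_hold]
    scaler = StandardScaler().fit(X_tr)
    clf = MLPClassifier(
        hidden_layer_sizes=hidden,
        max_iter=2000,
        random_state=int(seed) % (2**31),
        solver="lbfgs",
    )
    clf.fit(scaler.transform(X_tr), y_tr)
    acc = float(clf.score(scaler.transform(X_te), y_te))
    return AFLinkModel(scaler=scaler, classifier=clf, heldout_accuracy=acc)


def aflink_associate(
    trajectories: TrajectorySet,
    model: AFLinkModel,
    max_gap: int = 30,
    max_offset: float = 75.0,
    min_confidence: float = 0.9,
) -> TrajectorySet:
    """Merge fragmented identities whose link confidence clears the bar.

    Candidate pairs must be temporally disjoint with a frame gap of at
    most ``max_gap`` and a junction offset of at most ``max_offset`` px.
    Scored pairs enter a linear assignment on ``1 - confidence`` so each
    identity links forward and backward at most once; an accepted link
    relabels the successor with the predecessor's id.
    """
    ids = trajectories.ids
    if not ids:
        return trajectories.copy()
    trajs = {tid: trajectories.trajectory(tid) for tid in ids}
    spans = {tid: (min(trajs[tid]), max(trajs[tid])) for tid in ids}
    conf = np.full((len(ids), len(ids)), -1.0)
    for a, tid_a in enumerate(ids):
        for b, tid_b in enumerate(ids):
            if a == b:
                continue
            end_a, start_b = spans[tid_a][1], spans[tid_b][0]
            gap = start_b - end_a
            if gap < 1 or gap > max_gap:
                continue
            tail, head, deltas = aflink_features(trajs[tid_a], trajs[tid_b])
            if np.hypot(deltas[1], deltas[2]) > max_offset:
                continue
            c = model.predict_confidence(tail, head, deltas)
            if c >= min_confidence:
                conf[a, b] = c
    links: Dict[int, int] = {}
    if (conf >= 0).any():
        cost = np.where(conf >= 0, 1.0 - conf, 1e9)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if conf[r, c] >= 0:
                links[ids[c]] = ids[r]  # successor -> predecessor
    # resolve chains: follow predecessor links to the root id
    mapping = {}
    for tid in ids:
        root = tid
        seen = set()
        while root in links and root not in seen:
            seen.add(root)
            root = links[root]
        mapping[tid] = root
    return trajectories.relabel(mapping)
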