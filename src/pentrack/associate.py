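"""Per-frame association engine with a closed-pen track lifecycle.

Each frame: predict every track, build a gated combined cost matrix

    C = lambda * A_appearance + (1 - lambda) * A_motion

(appearance = cosine distance to the track's EMA template, motion =
gate-normalized squared Mahalanobis distance of the box under the
predicted Kalman state), solve a single global minimum-cost assignment,
and update matched tracks.

The lifecycle exploits the closed pen.  Because the population is fixed
and known (``n_max``):

* unmatched tracks are never deleted — an animal occluded for hundreds
  of frames keeps its track and re-matches on reappearance;
* new track ids are created only while fewer than ``n_max`` tracks
  exist, so the id count can never exceed the population;
* when detections are left unmatched at the id cap while occluded tracks
  exist, the admissibility gates are relaxed multiplicatively and the
  leftover assignment is retried, forcing matches within the fixed
  population instead of inventing identities.

A DeepSORT-style open-world lifecycle (finite ``max_age``, tentative
initialization, no id cap) is provided as a reference mode for
contrasting identity stability under long occlusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from . import motion
from .appearance import AppearanceState, appearance_cost_matrix, ema_update
from .io import Detection, TrajectorySet

__all__ = [
    "Track",
    "TrackerConfig",
    "Tracker",
    "combined_cost_matrix",
    "solve_assignment",
    "track_sequence",
]

logger = logging.getLogger(__name__)

_BIG = 1e9  # stands for an inadmissible pairing in the assignment matrix


@dataclass
class TrackerConfig:
    """Knobs of the association engine.

    ``lam`` weights appearance vs motion in the combined cost (appearance
    dominant by default); ``alpha`` is the EMA memory of the appearance
    template; ``gate_threshold`` is the chi-square admissibility gate on
    the squared Mahalanobis distance (0.95 quantile, 4 dof);
    ``appearance_gate`` is the largest admissible cosine distance.
    """

    n_max: int = 4
    lam: float = 0.98
    alpha: float = 0.9
    gate_threshold: float = motion.CHI2_GATE_4DOF
    appearance_gate: float = 0.4
    retry_relax_factor: float = 1.5
    max_retries: int = 3
    nsa: bool = True
    lifecycle: str = "capped"  # "capped" (closed pen) or "deepsort" (reference)
    max_age: int = 30          # deepsort mode only
    n_init: int = 3            # deepsort mode only

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")
        if self.lifecycle not in ("capped", "deepsort"):
            raise ValueError(f"unknown lifecycle {self.lifecycle!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "TrackerConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown tracker config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class Track:
    """One persistent identity and its motion/appearance state."""

    id: int
    kalman: motion.KalmanState
    appearance: AppearanceState
    status: str = "active"  # "active" | "occluded" | (deepsort) "tentative"
    frames_since_match: int = 0
    hits: int = 1
    history: Dict[int, Tuple[float, float, float, float]] = field(default_factory=dict)
    confidences: Dict[int, float] = field(default_factory=dict)


def combined_cost_matrix(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    config: TrackerConfig,
    gate_scale: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gated combined cost, shape ``(n_tracks, n_detections)``.

    Returns ``(C, admissible)``.  The motion cost is the squared
    Mahalanobis distance divided by ``gate_threshold`` (roughly [0, 1]
    inside the gate).  A pair is inadmissible when its gating distance
    exceeds ``gate_threshold * gate_scale`` or its appearance cost
    exceeds ``appearance_gate * gate_scale`` (the appearance gate only
    applies where both sides carry appearance vectors).
    """
    n_t, n_d = len(tracks), len(detections)
    C = np.zeros((n_t, n_d))
    admissible = np.ones((n_t, n_d), dtype=bool)
    if n_t == 0 or n_d == 0:
        return C, admissible
    A_a = appearance_cost_matrix(detections, tracks)
    meas = np.stack([d.to_xyah() for d in detections])
    A_m = np.empty((n_t, n_d))
    for i, tr in enumerate(tracks):
        A_m[i] = motion.gating_distance_multi(tr.kalman, meas)
    admissible &= A_m <= config.gate_threshold * gate_scale
    for i, tr in enumerate(tracks):
        if tr.appearance.initialized:
            for j, det in enumerate(detections):
                if det.embedding is not None and A_a[i, j] > config.appearance_gate * gate_scale:
                    admissible[i, j] = False
    C = config.lam * A_a + (1.0 - config.lam) * (A_m / config.gate_threshold)
    return C, admissible


def solve_assignment(
    C: np.ndarray, admissible: Optional[np.ndarray] = None
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Maximum-cardinality, minimum-cost matching over admissible entries.

    Returns ``(matches, unmatched_rows, unmatched_cols)`` with matches as
    ``(row, col)`` pairs.
    """
    C = np.asarray(C, dtype=float)
    n_r, n_c = C.shape
    if n_r == 0 or n_c == 0:
        return [], list(range(n_r)), list(range(n_c))
    if admissible is None:
        admissible = np.ones_like(C, dtype=bool)
    masked = np.where(admissible, C, _BIG)
    rows, cols = linear_sum_assignment(masked)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if admissible[r, c]]
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    unmatched_r = [r for r in range(n_r) if r not in matched_r]
    unmatched_c = [c for c in range(n_c) if c not in matched_c]
    return matches, unmatched_r, unmatched_c


class Tracker:
    """Stateful frame-by-frame tracker.

    ``affine_provider`` is an optional callable ``frame -> 2x3 array``
    supplying an externally estimated camera-motion transform applied to
    predicted track positions (identity when None; fixed overhead
    cameras need none).
    """

    def __init__(
        self,
        config: TrackerConfig,
        affine_provider: Optional[Callable[[int], np.ndarray]] = None,
    ):
        self.config = config
        self.affine_provider = affine_provider
        self.tracks: List[Track] = []
        self._finished: List[Track] = []  # deepsort mode: deleted confirmed tracks
        self._next_id = 1

    # ------------------------------------------------------------------
    def _new_track(self, det: Detection) -> Track:
        app = AppearanceState()
        if det.embedding is not None:
            app = ema_update(app, det.embedding, self.config.alpha)
        tr = Track(
            id=self._next_id,
            kalman=motion.kf_initiate(det),
            appearance=app,
            status="tentative" if self.config.lifecycle == "deepsort" else "active",
        )
        tr.history[det.frame] = det.bbox
        tr.confidences[det.frame] = det.confidence
        self._next_id += 1
        return tr

    def _update_track(self, tr: Track, det: Detection) -> None:
        if self.config.nsa:
            tr.kalman = motion.kf_update_nsa(tr.kalman, det)
        else:
            R = motion.measurement_noise(tr.kalman.mean[3])
            tr.kalman = motion.kf_update(tr.kalman, det, R)
        if det.embedding is not None:
            tr.appearance = ema_update(tr.appearance, det.embedding, self.config.alpha)
        tr.frames_since_match = 0
        tr.hits += 1
        if self.config.lifecycle == "deepsort" and tr.status == "tentative":
            if tr.hits >= self.config.n_init:
                tr.status = "active"
        else:
            tr.status = "active"
        tr.history[det.frame] = det.bbox
        tr.confidences[det.frame] = det.confidence

    # ------------------------------------------------------------------
    def step(self, detections: Sequence[Detection], frame: int) -> Dict[int, int]:
        """Process one frame; returns ``{track_id: detection_index}``."""
        cfg = self.config
        affine = self.affine_provider(frame) if self.affine_provider else None
        for tr in self.tracks:
            tr.kalman = motion.kf_predict(tr.kalman, affine=affine)

        C, adm = combined_cost_matrix(self.tracks, detections, cfg)
        matches, un_tracks, un_dets = solve_assignment(C, adm)
        assigned: Dict[int, int] = {}
        for ti, dj in matches:
            self._update_track(self.tracks[ti], detections[dj])
            assigned[self.tracks[ti].id] = dj

        if cfg.lifecycle == "capped":
            un_dets = self._capped_lifecycle(detections, un_tracks, un_dets, assigned, frame)
        else:
            un_dets = self._deepsort_lifecycle(detections, un_tracks, un_dets, assigned)
        if un_dets:
            logger.debug("frame %d: %d detections dropped", frame, len(un_dets))
        return assigned

    # ------------------------------------------------------------------
    def _capped_lifecycle(self, detections, un_tracks, un_dets, assigned, frame):
        cfg = self.config
        for ti in un_tracks:
            self.tracks[ti].frames_since_match += 1
            self.tracks[ti].status = "occluded"
        un_track_idx = list(un_tracks)

        # new ids only while the population cap allows it (confident first)
        un_dets = sorted(un_dets, key=lambda j: -detections[j].confidence)
        leftover: List[int] = []
        for dj in un_dets:
            if len(self.tracks) < cfg.n_max:
                tr = self._new_track(detections[dj])
                self.tracks.append(tr)
                assigned[tr.id] = dj
            else:
                leftover.append(dj)

        # at the cap: relax the gates and retry among occluded tracks
        retries = 0
        while leftover and un_track_idx and retries < cfg.max_retries:
            retries += 1
            scale = cfg.retry_relax_factor**retries
            sub_tracks = [self.tracks[i] for i in un_track_idx]
            sub_dets = [detections[j] for j in leftover]
            C, adm = combined_cost_matrix(sub_tracks, sub_dets, cfg, gate_scale=scale)
            matches, _, _ = solve_assignment(C, adm)
            if not matches:
                continue
            hit_t, hit_d = set(), set()
            for si, sj in matches:
                ti, dj = un_track_idx[si], leftover[sj]
                self._update_track(self.tracks[ti], detections[dj])
                assigned[self.tracks[ti].id] = dj
                hit_t.add(ti)
                hit_d.add(dj)
                logger.debug(
                    "retry %d matched track %d to detection %d", retries, self.tracks[ti].id, dj
                )
            un_track_idx = [i for i in un_track_idx if i not in hit_t]
            leftover = [j for j in leftover if j not in hit_d]
        if leftover and len(self.tracks) >= cfg.n_max:
            logger.warning(
                "%d unmatched detections dropped at the id cap (n_max=%d)",
                len(leftover),
                cfg.n_max,
            )
        return leftover

    # ------------------------------------------------------------------
    def _deepsort_lifecycle(self, detections, un_tracks, un_dets, assigned):
        cfg = self.config
        doomed = set()
        for ti in un_tracks:
            tr = self.tracks[ti]
            tr.frames_since_match += 1
            if tr.status == "tentative" or tr.frames_since_match > cfg.max_age:
                doomed.add(ti)
                if tr.status != "tentative":
                    self._finished.append(tr)
            else:
                tr.status = "occluded"
        self.tracks = [tr for i, tr in enumerate(self.tracks) if i not in doomed]
        for dj in un_dets:
            tr = self._new_track(detections[dj])
            self.tracks.append(tr)
            assigned[tr.id] = dj
        return []

    # ------------------------------------------------------------------
    def to_trajectories(self, fps: float = 25.0) -> TrajectorySet:
        out = TrajectorySet(fps=fps)
        for tr in self.tracks + self._finished:
            if self.config.lifecycle == "deepsort" and tr.status == "tentative":
                continue
            for frame, bbox in tr.history.items():
                out.add(tr.id, frame, bbox, tr.confidences[frame])
        return out


def track_sequence(
    detections_by_frame: Dict[int, Sequence[Detection]],
    config: TrackerConfig,
    fps: float = 25.0,
    affine_provider: Optional[Callable[[int], np.ndarray]] = None,
) -> TrajectorySet:
    """Run the tracker over a whole sequence and return its trajectories.

    Frames are processed in increasing order; frames absent from the map
    (no detections at all) are stepped with an empty list so occlusion
    counters advance.
    """
    tracker = Tracker(config, affine_provider=affine_provider)
    if not detections_by_frame:
        return TrajectorySet(fps=fps)
    lo, hi = min(detections_by_frame), max(detections_by_frame)
    for frame in range(lo, hi + 1):
        tracker.step(detections_by_frame.get(frame, []), frame)
    return tracker.to_trajectories(fps=fps)
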