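"""Synthetic closed-pen scenario generator.

Emulates what an overhead camera plus a single-class detector would
produce for a pen with a fixed, known population: every animal is present
in every ground-truth frame (nothing enters or leaves), motion is a
smooth bounded random walk, and the detection stream exhibits the
failure modes the tracker must survive — occlusion episodes during which
an animal yields no detections for tens to hundreds of frames, bounding
box jitter, sporadic baseline misses, and confidence that sags when
animals overlap.  Per-identity appearance embeddings are a prototype
direction on the unit sphere plus isotropic noise, standing in for a
trained re-identification extractor.

Motion model: per-animal Ornstein–Uhlenbeck velocity process

    dv = -relax_rate * v * dt + vel_noise * sqrt(dt) * dW

with reflecting pen boundaries, giving a stationary per-component speed
scale of ``vel_noise / sqrt(2 * relax_rate)`` px/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import Bbox, Detection, TrajectorySet

__all__ = ["SimConfig", "Scenario", "simulate_pen", "inject_occlusion", "subsample_fps"]


@dataclass
class SimConfig:
    """Scenario parameters; defaults describe a quiet 4-animal finishing pen.

    Rates and scales are per real-world unit (seconds, pixels); the
    occlusion event rate is per animal-minute.
    """

    n_animals: int = 4
    pen: Bbox = (0.0, 0.0, 1280.0, 720.0)
    fps: float = 25.0
    duration: float = 60.0
    # motion (Ornstein–Uhlenbeck velocity, px/s units)
    mean_speed: float = 35.0
    relax_rate: float = 0.5
    vel_noise: Optional[float] = None  # derived from mean_speed when None
    # body geometry (pixels)
    body_length_mean: float = 130.0
    body_length_sd: float = 12.0
    body_height_mean: float = 80.0
    body_height_sd: float = 8.0
    # occlusion episodes
    occlusion_rate: float = 2.0        # events per animal-minute
    occlusion_dur_range: Tuple[int, int] = (25, 250)  # frames
    occlusion_miss_prob: float = 1.0   # per-frame miss prob while occluded
    # detection noise
    jitter_sd: float = 1.5             # px, on box corner position
    baseline_miss_rate: float = 0.01
    false_positive_rate: float = 0.0   # expected spurious boxes per frame
    conf_base: float = 0.95
    conf_overlap_penalty: float = 0.6
    conf_floor: float = 0.3
    # appearance embeddings
    embedding_dim: int = 128
    embedding_noise_sd: float = 0.05   # sigma_e, per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.duration * self.fps < 1:
            raise ValueError("duration * fps must be >= 1 frame")
        for name in (
            "mean_speed", "relax_rate", "occlusion_rate", "occlusion_miss_prob",
            "jitter_sd", "baseline_miss_rate", "false_positive_rate",
            "embedding_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vel_noise is None:
            self.vel_noise = self.mean_speed * np.sqrt(2.0 * self.relax_rate)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class Scenario:
    """One simulated sequence: truth, noisy detections, identity prototypes.

    ``occlusion_windows`` maps animal id -> list of (start, end) frame
    windows during which that animal's detections were suppressed.
    """

    gt: TrajectorySet
    detections: Dict[int, List[Detection]]
    prototypes: Dict[int, np.ndarray]
    config: SimConfig
    occlusion_windows: Dict[int, List[Tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        lo, hi = self.gt.frame_range
        return hi - lo + 1


def _iou(a: Bbox, b: Bbox) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter) if inter > 0 else 0.0


def _overlap_fraction(i: int, boxes: List[Bbox]) -> float:
    """Largest fraction of box i's area covered by any other box."""
    ax, ay, aw, ah = boxes[i]
    best = 0.0
    for j, (bx, by, bw, bh) in enumerate(boxes):
        if j == i:
            continue
        ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
        iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
        best = max(best, ix * iy / (aw * ah))
    return best


def _sample_occlusion_windows(rng, cfg: SimConfig) -> List[List[Tuple[int, int]]]:
    """Per-animal list of non-overlapping (start, end) occlusion windows."""
    p_start = cfg.occlusion_rate / (60.0 * cfg.fps)
    lo, hi = cfg.occlusion_dur_range
    windows: List[List[Tuple[int, int]]] = []
    for _ in range(cfg.n_animals):
        mine: List[Tuple[int, int]] = []
        t = 0
        while t < cfg.n_frames:
            if rng.random() < p_start:
                dur = int(rng.integers(lo, hi + 1))
                mine.append((t, min(t + dur, cfg.n_frames)))
                t += dur
            t += 1
        windows.append(mine)
    return windows


def simulate_pen(config: SimConfig) -> Scenario:
    """Generate one scenario; identical configs (incl. seed) give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_animals, cfg.n_frames
    dt = 1.0 / cfg.fps
    px, py, pw, ph = cfg.pen

    widths = np.clip(rng.normal(cfg.body_length_mean, cfg.body_length_sd, n), 20.0, None)
    heights = np.clip(rng.normal(cfg.body_height_mean, cfg.body_height_sd, n), 15.0, None)

    # initial positions uniform in the pen (box fully inside), velocities stationary
    cx = rng.uniform(px + widths / 2, px + pw - widths / 2)
    cy = rng.uniform(py + heights / 2, py + ph - heights / 2)
    sd_v = cfg.vel_noise / np.sqrt(2.0 * cfg.relax_rate)
    vx = rng.normal(0.0, sd_v, n)
    vy = rng.normal(0.0, sd_v, n)

    prototypes = rng.standard_normal((n, cfg.embedding_dim))
    prototypes /= np.linalg.norm(prototypes, axis=1, keepdims=True)

    occl = _sample_occlusion_windows(rng, cfg)
    occluded_at = [np.zeros(T, dtype=bool) for _ in range(n)]
    for i, wins in enumerate(occl):
        for s, e in wins:
            occluded_at[i][s:e] = True

    gt = TrajectorySet(fps=cfg.fps)
    detections: Dict[int, List[Detection]] = {}
    sq = np.sqrt(dt)
    for t in range(T):
        boxes: List[Bbox] = []
        for i in range(n):
            boxes.append((cx[i] - widths[i] / 2, cy[i] - heights[i] / 2, widths[i], heights[i]))
            gt.add(i + 1, t, boxes[i])
        dets: List[Detection] = []
        for i in range(n):
            if occluded_at[i][t] and rng.random() < cfg.occlusion_miss_prob:
                continue
            if rng.random() < cfg.baseline_miss_rate:
                continue
            l, tp, w, h = boxes[i]
            jl, jt = rng.normal(0.0, cfg.jitter_sd, 2)
            jw, jh = rng.normal(0.0, cfg.jitter_sd / 2, 2)
            bbox = (l + jl, tp + jt, max(w + jw, 4.0), max(h + jh, 4.0))
            conf = float(
                np.clip(
                    cfg.conf_base - cfg.conf_overlap_penalty * _overlap_fraction(i, boxes),
                    cfg.conf_floor,
                    1.0,
                )
            )
            emb = prototypes[i] + cfg.embedding_noise_sd * rng.standard_normal(cfg.embedding_dim)
            dets.append(
                Detection(frame=t, bbox=bbox, confidence=conf, embedding=emb, source_id=i + 1)
            )
        n_fp = rng.poisson(cfg.false_positive_rate)
        for _ in range(n_fp):
            w = float(rng.uniform(30, cfg.body_length_mean))
            h = float(rng.uniform(20, cfg.body_height_mean))
            l = float(rng.uniform(px, px + pw - w))
            tp = float(rng.uniform(py, py + ph - h))
            emb = rng.standard_normal(cfg.embedding_dim)
            dets.append(
                Detection(
                    frame=t,
                    bbox=(l, tp, w, h),
                    confidence=float(rng.uniform(cfg.conf_floor, 0.6)),
                    embedding=emb,
                    source_id=None,
                )
            )
        detections[t] = dets

        # advance the OU walk, reflecting box centers off the pen walls
        vx += -cfg.relax_rate * vx * dt + cfg.vel_noise * sq * rng.standard_normal(n)
        vy += -cfg.relax_rate * vy * dt + cfg.vel_noise * sq * rng.standard_normal(n)
        cx += vx * dt
        cy += vy * dt
        for i in range(n):
            lo_x, hi_x = px + widths[i] / 2, px + pw - widths[i] / 2
            lo_y, hi_y = py + heights[i] / 2, py + ph - heights[i] / 2
            if cx[i] < lo_x:
                cx[i], vx[i] = 2 * lo_x - cx[i], -vx[i]
            elif cx[i] > hi_x:
                cx[i], vx[i] = 2 * hi_x - cx[i], -vx[i]
            if cy[i] < lo_y:
                cy[i], vy[i] = 2 * lo_y - cy[i], -vy[i]
            elif cy[i] > hi_y:
                cy[i], vy[i] = 2 * hi_y - cy[i], -vy[i]
            cx[i] = np.clip(cx[i], lo_x, hi_x)
            cy[i] = np.clip(cy[i], lo_y, hi_y)

    protos = {i + 1: prototypes[i] for i in range(n)}
    windows = {i + 1: list(occl[i]) for i in range(n)}
    return Scenario(
        gt=gt, detections=detections, prototypes=protos, config=cfg, occlusion_windows=windows
    )


def inject_occlusion(
    scenario: Scenario, animal_id: int, start_frame: int, duration: int
) -> Dict[int, List[Detection]]:
    """Return a detection map with one animal's detections removed in
    ``[start_frame, start_frame + duration)``; the ground truth is untouched."""
    if animal_id not in scenario.gt:
        raise KeyError(f"unknown ground-truth id {animal_id}")
    lo, hi = scenario.gt.frame_range
    end = start_frame + duration
    if start_frame < lo or end > hi + 1:
        raise ValueError(f"window [{start_frame}, {end}) outside frame range [{lo}, {hi}]")
    out: Dict[int, List[Detection]] = {}
    for frame, dets in scenario.detections.items():
        if start_frame <= frame < end:
            out[frame] = [d for d in dets if d.source_id != animal_id]
        else:
            out[frame] = list(dets)
    return out


def subsample_fps(scenario: Scenario, factor: int) -> Scenario:
    """Keep every ``factor``-th frame and renumber consecutively.

    Models a lower-frame-rate camera: inter-frame displacements grow by
    ``factor`` while the tracker sees proportionally fewer observations.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return scenario
    new_fps = scenario.config.fps / factor
    gt = TrajectorySet(fps=new_fps)
    for tid in scenario.gt.ids:
        for frame, bbox in scenario.gt.trajectory(tid).items():
            if frame % factor == 0:
                gt.add(tid, frame // factor, bbox)
    detections: Dict[int, List[Detection]] = {}
    for frame, dets in scenario.detections.items():
        if frame % factor == 0:
            detections[frame // factor] = [replace(d, frame=frame // factor) for d in dets]
    cfg = replace(
        scenario.config,
        fps=new_fps,
        duration=scenario.config.duration,
    )
    windows = {
        tid: [(-(-s // factor), -(-e // factor)) for s, e in wins]
        for tid, wins in scenario.occlusion_windows.items()
    }
    return Scenario(
        gt=gt,
        detections=detections,
        prototypes=scenario.prototypes,
        config=cfg,
        occlusion_windows=windows,
    )
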