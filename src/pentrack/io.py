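"""Data model and file I/O for detections, trajectories and configs.

File formats follow the MOTChallenge plain-text dialects::

    det:    frame,id,left,top,width,height,conf,-1,-1,-1   (id ignored)
    gt/res: frame,id,left,top,width,height,conf,-1,-1,-1

Frame indices are 1-based on disk and 0-based in memory; the conversion
happens only here, at the I/O boundary.  Bounding boxes are
``(left, top, width, height)`` in pixels with a top-left origin; a point
``(x, y)`` lies inside a box iff ``left <= x < left+w`` and
``top <= y < top+h``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

Bbox = Tuple[float, float, float, float]

__all__ = [
    "Detection",
    "TrajectorySet",
    "SceneConfig",
    "FormatError",
    "read_detections",
    "read_ground_truth",
    "read_result",
    "write_result",
    "read_embeddings",
    "write_embeddings",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Detection:
    """One candidate bounding box in one frame.

    Parameters
    ----------
    frame:
        0-based frame index.
    bbox:
        ``(left, top, width, height)`` in pixels; ``width, height > 0``.
    confidence:
        Detector confidence in ``[0, 1]``; drives the adaptive measurement
        noise of the Kalman update.
    embedding:
        Optional unit-L2-norm appearance vector (re-identification feature).
    source_id:
        Ground-truth identity when the detection comes from the simulator;
        never consumed by the tracker.
    """

    frame: int
    bbox: Bbox
    confidence: float = 1.0
    embedding: Optional[np.ndarray] = None
    source_id: Optional[int] = None

    def __post_init__(self) -> None:
        left, top, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate bbox {self.bbox}: width and height must be > 0")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            norm = float(np.linalg.norm(self.embedding))
            if norm == 0:
                raise ValueError("embedding has zero norm")
            self.embedding = self.embedding / norm

    @property
    def center(self) -> Tuple[float, float]:
        left, top, w, h = self.bbox
        return (left + w / 2.0, top + h / 2.0)

    def to_xyah(self) -> np.ndarray:
        """Convert to (center-x, center-y, aspect ratio w/h, height)."""
        left, top, w, h = self.bbox
        return np.array([left + w / 2.0, top + h / 2.0, w / h, h], dtype=float)


def bbox_from_xyah(xyah: Sequence[float]) -> Bbox:
    cx, cy, a, h = xyah
    w = a * h
    return (cx - w / 2.0, cy - h / 2.0, w, h)


class TrajectorySet:
    """Identity-indexed trajectories: ``id -> (frame -> bbox)``.

    The common currency between the tracker, the evaluation metrics and
    the zone-occupancy analysis.  Frames within one id are kept sorted;
    an optional per-(id, frame) confidence is stored alongside.
    """

    def __init__(self, fps: float = 25.0):
        self.fps = float(fps)
        self._data: Dict[int, Dict[int, Bbox]] = {}
        self._conf: Dict[int, Dict[int, float]] = {}

    # -- construction ---------------------------------------------------
    def add(self, tid: int, frame: int, bbox: Bbox, confidence: float = 1.0) -> None:
        left, top, w, h = bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate bbox {bbox} for id {tid} frame {frame}")
        frames = self._data.setdefault(tid, {})
        if frame in frames:
            raise FormatError(f"duplicate entry for id {tid} at frame {frame}")
        frames[frame] = (float(left), float(top), float(w), float(h))
        self._conf.setdefault(tid, {})[frame] = float(confidence)

    # -- access ---------------------------------------------------------
    @property
    def ids(self) -> List[int]:
        return sorted(self._data)

    def frames_of(self, tid: int) -> List[int]:
        return sorted(self._data[tid])

    def trajectory(self, tid: int) -> Dict[int, Bbox]:
        return dict(sorted(self._data[tid].items()))

    def confidence(self, tid: int, frame: int) -> float:
        return self._conf[tid][frame]

    def __contains__(self, tid: int) -> bool:
        return tid in self._data

    def __len__(self) -> int:
        return len(self._data)

    def n_boxes(self) -> int:
        return sum(len(v) for v in self._data.values())

    @property
    def frame_range(self) -> Tuple[int, int]:
        frames = [f for traj in self._data.values() for f in traj]
        if not frames:
            return (0, -1)
        return (min(frames), max(frames))

    def boxes_in_frame(self, frame: int) -> Dict[int, Bbox]:
        return {tid: traj[frame] for tid, traj in self._data.items() if frame in traj}

    def copy(self) -> "TrajectorySet":
        out = TrajectorySet(fps=self.fps)
        for tid, traj in self._data.items():
            for frame, bbox in traj.items():
                out.add(tid, frame, bbox, self._conf[tid][frame])
        return out

    def relabel(self, mapping: Mapping[int, int]) -> "TrajectorySet":
        """Return a copy with ids renamed through ``mapping`` (others kept)."""
        out = TrajectorySet(fps=self.fps)
        for tid, traj in self._data.items():
            new = mapping.get(tid, tid)
            for frame, bbox in traj.items():
                out.add(new, frame, bbox, self._conf[tid][frame])
        return out


@dataclass
class SceneConfig:
    """Static description of the pen scene.

    ``n_max`` is the known (fixed) population of the pen: no animal enters
    or leaves, which is what licenses the no-deletion, id-capped track
    lifecycle.  ``pen`` is ``(left, top, width, height)`` in pixels.
    """

    n_max: int = 4
    fps: float = 25.0
    pen: Bbox = (0.0, 0.0, 1280.0, 720.0)
    embedding_dim: int = 128

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "SceneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"n_max", "fps", "pen", "embedding_dim"}
        bad = set(raw) - known
        if bad:
            raise FormatError(f"unknown scene config keys: {sorted(bad)}")
        if "pen" in raw:
            raw["pen"] = tuple(float(v) for v in raw["pen"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_rows(path: str) -> List[Tuple[int, int, float, float, float, float, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: expected >= 7 comma-separated fields")
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                l, t, w, h, conf = (float(p) for p in parts[2:7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if frame < 1:
                raise FormatError(f"{path}:{lineno}: frame index {frame} is not 1-based positive")
            rows.append((frame, tid, l, t, w, h, conf))
    return rows


def read_embeddings(path: str) -> np.ndarray:
    """Load a dense embedding sidecar (text CSV or ``.npy``), one row per
    detection line, rows L2-renormalized."""
    if path.endswith(".npy"):
        mat = np.load(path)
    else:
        mat = np.loadtxt(path, delimiter=",", ndmin=2)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise FormatError(f"{path}: zero-norm embedding row")
    return mat / norms


def write_embeddings(mat: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), delimiter=",", fmt="%.8f")


def read_detections(path: str, embedding_path: Optional[str] = None) -> Dict[int, List[Detection]]:
    """Read a detection file, optionally paired with an embedding sidecar.

    Returns detections grouped by 0-based frame, sorted by frame; the id
    column of det files is ignored.  The sidecar must have exactly one row
    per detection line, in file order.
    """
    rows = _parse_rows(path)
    embeddings = None
    if embedding_path is not None:
        embeddings = read_embeddings(embedding_path)
        if len(embeddings) != len(rows):
            raise FormatError(
                f"{embedding_path}: {len(embeddings)} embedding rows for {len(rows)} detections"
            )
    by_frame: Dict[int, List[Detection]] = {}
    for i, (frame, _tid, l, t, w, h, conf) in enumerate(rows):
        det = Detection(
            frame=frame - 1,
            bbox=(l, t, w, h),
            confidence=min(max(conf, 0.0), 1.0),
            embedding=None if embeddings is None else embeddings[i],
        )
        by_frame.setdefault(frame - 1, []).append(det)
    return dict(sorted(by_frame.items()))


def _read_trajectories(path: str, fps: float) -> TrajectorySet:
    out = TrajectorySet(fps=fps)
    for frame, tid, l, t, w, h, conf in _parse_rows(path):
        out.add(tid, frame - 1, (l, t, w, h), conf)
    return out


def read_ground_truth(path: str, fps: float = 25.0) -> TrajectorySet:
    """Read a ground-truth file into a :class:`TrajectorySet`.

    Rows may arrive in any order; duplicate ``(frame, id)`` rows are a
    consistency error.
    """
    return _read_trajectories(path, fps)


def read_result(path: str, fps: float = 25.0) -> TrajectorySet:
    """Read a tracker result file (same dialect as ground truth)."""
    return _read_trajectories(path, fps)


def write_result(trajectories: TrajectorySet, path: str) -> None:
    """Write a result file, rows sorted by (frame, id), 6-decimal floats."""
    rows = []
    for tid in trajectories.ids:
        traj = trajectories.trajectory(tid)
        for frame, (l, t, w, h) in traj.items():
            conf = trajectories.confidence(tid, frame)
            rows.append((frame + 1, tid, l, t, w, h, conf))
    rows.sort(key=lambda r: (r[0], r[1]))
    dirname = os.path.dirname(os.path.abspath(path))
    os.makedirs(dirname, exist_ok=True)
    with open(path, "w") as fh:
        for frame, tid, l, t, w, h, conf in rows:
            fh.write(f"{frame},{tid},{l:.6f},{t:.6f},{w:.6f},{h:.6f},{conf:.6f},-1,-1,-1\n")
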