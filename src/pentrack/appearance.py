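"""Per-track appearance templates and the cosine re-identification cost.

Each track carries an exponential-moving-average (EMA) of the unit-norm
appearance embeddings of the detections it has absorbed::

    e_t = alpha * e_{t-1} + (1 - alpha) * f_t

The raw EMA accumulator follows this recursion exactly (so after k
constant-input updates it equals ``alpha^k e_0 + (1-alpha) * sum_{j<k}
alpha^j f``); the template used for matching is its L2 normalization,
keeping the cosine cost in [0, 2].

The association cost between a detection embedding ``r`` and a track
template ``e`` is the cosine distance ``1 - r . e``; the per-detection
minimum over tracks is what the matcher minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["AppearanceState", "ema_update", "appearance_cost", "appearance_cost_matrix"]


@dataclass
class AppearanceState:
    """EMA appearance template of one track.

    ``raw`` is the unnormalized EMA accumulator; ``vector`` its unit-norm
    projection (the matching template).
    """

    raw: Optional[np.ndarray] = None
    vector: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.raw is not None and self.vector is None:
            self.vector = self.raw / np.linalg.norm(self.raw)

    @property
    def initialized(self) -> bool:
        return self.raw is not None


def ema_update(e_prev: AppearanceState, f: np.ndarray, alpha: float) -> AppearanceState:
    """Blend a new embedding into the template.

    ``alpha`` is the memory weight: 0 replaces the template outright, 1
    freezes it.  An uninitialized template is set to ``f`` directly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    f = np.asarray(f, dtype=float)
    f = f / np.linalg.norm(f)
    if not e_prev.initialized:
        return AppearanceState(raw=f.copy())
    raw = alpha * e_prev.raw + (1.0 - alpha) * f
    norm = np.linalg.norm(raw)
    if norm == 0:  # antipodal degenerate case; keep the old template direction
        return AppearanceState(raw=raw, vector=e_prev.vector.copy())
    return AppearanceState(raw=raw)


def appearance_cost(r: np.ndarray, e: AppearanceState) -> float:
    """Cosine distance ``1 - r . e``; 1 (neutral) if ``e`` is uninitialized."""
    if not e.initialized:
        return 1.0
    return float(1.0 - np.dot(np.asarray(r, dtype=float), e.vector))


def appearance_cost_matrix(detections: Sequence, tracks: Sequence) -> np.ndarray:
    """Cosine cost matrix, shape ``(n_tracks, n_detections)``.

    Detections without an embedding and tracks without an initialized
    template get the neutral cost 1, making the combined cost effectively
    motion-driven for those pairs.
    """
    n_t, n_d = len(tracks), len(detections)
    A = np.ones((n_t, n_d))
    if n_t == 0 or n_d == 0:
        return A
    states = [getattr(t, "appearance", t) for t in tracks]
    have_e = [
        j for j, d in enumerate(detections) if getattr(d, "embedding", None) is not None
    ]
    if not have_e:
        return A
    R = np.stack([detections[j].embedding for j in have_e])
    for i, st in enumerate(states):
        if st.initialized:
            A[i, have_e] = 1.0 - R @ st.vector
    return A
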