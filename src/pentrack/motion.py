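"""Constant-velocity Kalman filter with confidence-adaptive measurement noise.

The state is the 8-vector ``(cx, cy, a, h, v_cx, v_cy, v_a, v_h)`` where
``a = width/height`` and ``h`` is the box height in pixels — the
parameterization used throughout the SORT/DeepSORT/StrongSORT family.
Process and measurement noise scale with the box height, so the filter is
size-adaptive.

The measurement update is *noise-scale adaptive* (NSA): the measurement
noise covariance is scaled by ``(1 - c)`` where ``c`` is the detection
confidence, so confident detections pull the posterior hard toward the
measurement (``c = 1`` reproduces it exactly) while low-confidence ones
are discounted toward the motion prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import Detection

__all__ = [
    "KalmanState",
    "CHI2_GATE_4DOF",
    "kf_initiate",
    "kf_predict",
    "kf_update",
    "kf_update_nsa",
    "gating_distance",
]

# chi-square 0.95 quantile, 4 degrees of freedom: the default admissibility
# gate on the squared Mahalanobis distance of the 4-D box measurement
CHI2_GATE_4DOF = 9.4877

_STD_WEIGHT_POSITION = 1.0 / 20.0
_STD_WEIGHT_VELOCITY = 1.0 / 160.0

_NDIM = 4
_F = np.eye(2 * _NDIM)
for _i in range(_NDIM):
    _F[_i, _NDIM + _i] = 1.0
_H = np.eye(_NDIM, 2 * _NDIM)


@dataclass
class KalmanState:
    """Gaussian state estimate: 8-vector mean and 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(8)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(8, 8)


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def kf_initiate(detection: Detection) -> KalmanState:
    """Create a track state from an unassociated detection.

    Positional components come straight from the box; velocities start at
    zero with a deliberately wide prior so the first few updates can pin
    them down.  All standard deviations scale with the box height.
    """
    xyah = detection.to_xyah()
    mean = np.zeros(8)
    mean[:4] = xyah
    h = xyah[3]
    std = np.array(
        [
            2 * _STD_WEIGHT_POSITION * h,
            2 * _STD_WEIGHT_POSITION * h,
            1e-2,
            2 * _STD_WEIGHT_POSITION * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * _STD_WEIGHT_VELOCITY * h,
        ]
    )
    return KalmanState(mean=mean, covariance=np.diag(std**2))


def _motion_noise(h: float) -> np.ndarray:
    std = np.array(
        [
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-2,
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_VELOCITY * h,
            _STD_WEIGHT_VELOCITY * h,
            1e-5,
            _STD_WEIGHT_VELOCITY * h,
        ]
    )
    return np.diag(std**2)


def measurement_noise(h: float) -> np.ndarray:
    """Baseline measurement noise R for a box of height ``h``."""
    std = np.array(
        [
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-1,
            _STD_WEIGHT_POSITION * h,
        ]
    )
    return np.diag(std**2)


def kf_predict(state: KalmanState, affine: np.ndarray | None = None) -> KalmanState:
    """Advance the state one frame under constant-velocity dynamics.

    ``affine`` is an optional 2x3 camera-motion matrix applied to the
    predicted box center (a hook for externally estimated frame
    registration; identity for fixed overhead cameras).
    """
    mean = _F @ state.mean
    cov = _symmetrize(_F @ state.covariance @ _F.T + _motion_noise(state.mean[3]))
    if affine is not None:
        A = np.asarray(affine, dtype=float).reshape(2, 3)
        mean[:2] = A[:, :2] @ mean[:2] + A[:, 2]
    return KalmanState(mean=mean, covariance=cov)


def project(state: KalmanState, extra_R: np.ndarray | None = None):
    """Project the state onto measurement space; returns (mean, S)."""
    S = _H @ state.covariance @ _H.T
    if extra_R is not None:
        S = S + extra_R
    return _H @ state.mean, _symmetrize(S)


def kf_update(state: KalmanState, detection: Detection, R: np.ndarray) -> KalmanState:
    """Textbook Kalman measurement update with noise covariance ``R``."""
    z = detection.to_xyah()
    proj_mean, S = project(state, R)
    try:
        chol = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular innovation covariance: {exc}") from exc
    K = scipy.linalg.cho_solve(chol, (state.covariance @ _H.T).T, check_finite=False).T
    innovation = z - proj_mean
    mean = state.mean + K @ innovation
    cov = _symmetrize(state.covariance - K @ S @ K.T)
    return KalmanState(mean=mean, covariance=cov)


def kf_update_nsa(state: KalmanState, detection: Detection) -> KalmanState:
    """Confidence-adaptive update: measurement noise ``(1 - c) * R``.

    With ``c = 1`` the noise vanishes and the posterior position equals
    the measurement; with ``c = 0`` this is the plain update with ``R``.
    """
    R = (1.0 - detection.confidence) * measurement_noise(state.mean[3])
    return kf_update(state, detection, R)


def gating_distance(state: KalmanState, detection: Detection) -> float:
    """Squared Mahalanobis distance of a detection under the predicted state.

    Computed over the projected 4-D measurement distribution (position,
    aspect, height); used as the motion admissibility gate.
    """
    return float(gating_distance_multi(state, detection.to_xyah()[None, :])[0])


def gating_distance_multi(state: KalmanState, measurements: np.ndarray) -> np.ndarray:
    """Vectorized :func:`gating_distance` for an ``(n, 4)`` array."""
    proj_mean, S = project(state, measurement_noise(state.mean[3]))
    try:
        chol = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"non-invertible innovation covariance: {exc}") from exc
    d = np.asarray(measurements, dtype=float) - proj_mean
    sol = scipy.linalg.cho_solve(chol, d.T, check_finite=False)
    return np.sum(d.T * sol, axis=0)
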