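"""Retinal boundary tracking: measurement, Kalman fusion, and control.

The boundary position is measured from a segmented A-scan by averaging the
bottommost pixel of the adjacent upper layer and the topmost pixel of the
adjacent lower layer.  The boundary velocity is measured from the
cross-correlation shift between two consecutive A-scans, minus the motor
motion commanded in between.  A constant-velocity Kalman filter fuses the
two:

    x_k = F x_{k-1} + B u_{k-1} + w_k,   F = [[1, dt], [0, 1]],  B = [1, 0]^T
    z_k = H x_k + n_k,                   H = I_2

with process noise Q = G G^T sigma_a^2, G = [dt^2/2, dt]^T (white
acceleration), and diagonal measurement covariance R.  The predict/correct
recursion is the standard one with gain K = P H^T (H P H^T + R)^-1.

The motor command is proportional control u = c (x_target - x_est), clipped
to the per-cycle step the motor's velocity limit allows.  All positions are
pixels of optical path; one control unit u moves the measured boundary by
one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import AScan, LabelMask, LAYER_NAMES

__all__ = [
    "KalmanModel",
    "KalmanState",
    "ControlLaw",
    "measure_boundary",
    "measure_velocity",
    "kalman_step",
    "kalman_predict_correct",
    "control_step",
    "xcorr_shift",
]


def _check_spd(M: np.ndarray, name: str, strict: bool) -> None:
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(M)
    if strict and eig.min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    if not strict and eig.min() < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")


@dataclass
class KalmanModel:
    """Constant-velocity model for one boundary, in pixels and seconds.

    ``sigma_a`` (px/s^2) scales the white-acceleration process noise; the
    default allows ~50 um maneuvers within 100 ms at 2.7 um/px.  ``r_pos``
    and ``r_vel`` are measurement variances of the CNN position (px^2) and
    the cross-correlation velocity ((px/s)^2).
    """

    dt: float = 0.003
    sigma_a: float = 4000.0
    r_pos: float = 1.0
    r_vel: float = 40000.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.r_pos <= 0 or self.r_vel <= 0:
            raise ValueError("measurement variances must be positive")

    @property
    def F(self) -> np.ndarray:
        return np.array([[1.0, self.dt], [0.0, 1.0]])

    @property
    def B(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    @property
    def H(self) -> np.ndarray:
        return np.eye(2)

    @property
    def Q(self) -> np.ndarray:
        G = np.array([[self.dt**2 / 2.0], [self.dt]])
        return G @ G.T * self.sigma_a**2

    @property
    def R(self) -> np.ndarray:
        return np.diag([self.r_pos, self.r_vel])


@dataclass
class KalmanState:
    """Estimated boundary position (px) and velocity (px/s) with covariance."""

    x: float
    v: float
    P: np.ndarray = field(default_factory=lambda: np.eye(2) * 100.0)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        _check_spd(self.P, "P", strict=False)

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.x, self.v])


@dataclass
class ControlLaw:
    """Proportional depth-targeting law with actuator step saturation."""

    gain: float = 0.5
    x_target: float = 160.0
    u_max: float = 13.88  # px per cycle; 12.5 mm/s * 3 ms / 2.7 um

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.u_max <= 0:
            raise ValueError("gain and u_max must be positive")


def measure_boundary(mask: LabelMask, upper_class: int, lower_class: int) -> float:
    """Boundary position from a segmented mask, or NaN if either class is
    absent (an invalid measurement, not an error).

    Averages the bottommost pixel index of the upper class and the topmost
    pixel index of the lower class — applied literally even on noisy masks
    where the two overlap.
    """
    if lower_class != upper_class + 1:
        raise ValueError(
            f"classes must be adjacent in layer order, got "
            f"{LAYER_NAMES[upper_class]} / {LAYER_NAMES[lower_class]}"
        )
    labels = mask.labels
    upper_idx = np.flatnonzero(labels == upper_class)
    lower_idx = np.flatnonzero(labels == lower_class)
    if upper_idx.size == 0 or lower_idx.size == 0:
        return float("nan")
    return (float(upper_idx[-1]) + float(lower_idx[0])) / 2.0


def xcorr_shift(a: np.ndarray, b: np.ndarray) -> int:
    """Integer displacement of ``a`` relative to ``b`` maximizing their
    cross-correlation (positive = ``a`` shifted toward larger depth).
    Ties break toward the smallest absolute displacement."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = len(a)
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=n)
    lags = np.arange(n)
    lags[lags > n // 2] -= n  # circular lag -> signed
    corr = np.round(corr, 9)
    best = np.flatnonzero(corr == corr.max())
    return int(lags[best[np.argmin(np.abs(lags[best]))]])


def measure_velocity(
    ascan_t: AScan | np.ndarray,
    ascan_prev: AScan | np.ndarray,
    u_prev: float,
    dt: float,
) -> tuple[float, bool]:
    """Boundary velocity (px/s) from two consecutive A-scans.

    The cross-correlation shift between the scans is the total apparent
    displacement; subtracting the motor step commanded in between leaves the
    sample's own motion.  Returns ``(velocity, ok)``; a zero-energy input
    yields ``(0.0, False)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = ascan_t.intensity if isinstance(ascan_t, AScan) else np.asarray(ascan_t)
    b = ascan_prev.intensity if isinstance(ascan_prev, AScan) else np.asarray(ascan_prev)
    if len(a) != len(b):
        raise ValueError("A-scan lengths differ")
    if not np.any(a != 0) or not np.any(b != 0):
        return 0.0, False
    shift = xcorr_shift(a, b)
    return (shift - u_prev) / dt, True


def kalman_predict_correct(
    mean: np.ndarray,
    P: np.ndarray,
    F: np.ndarray,
    Q: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
    z: np.ndarray,
    Bu: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One generic predict/correct cycle (any state dimension).

    Used directly for reduced (e.g. scalar position-only) filters; the
    2-state boundary tracker wraps it via :func:`kalman_step`.
    """
    mean = F @ mean
    if Bu is not None:
        mean = mean + Bu
    P = F @ P @ F.T + Q
    S = H @ P @ H.T + R
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = P @ H.T @ np.linalg.inv(S)
    mean = mean + K @ (np.asarray(z, dtype=np.float64) - H @ mean)
    I = np.eye(P.shape[0])
    P = (I - K @ H) @ P
    P = (P + P.T) / 2.0
    return mean, P


def kalman_step(
    state: KalmanState,
    model: KalmanModel,
    z: tuple[float, float],
    u_prev: float = 0.0,
) -> KalmanState:
    """Advance the boundary tracker by one control cycle.

    ``z = (position, velocity)``; a NaN position marks a missing CNN
    measurement, in which case the correction uses the velocity row of H
    only and the position coasts on the prediction.
    """
    z_pos, z_vel = z
    if not np.isfinite(z_vel):
        raise ValueError("velocity measurement must be finite")
    if np.isfinite(z_pos):
        H, R, zv = model.H, model.R, np.array([z_pos, z_vel])
    else:
        H = model.H[1:, :]
        R = model.R[1:, 1:]
        zv = np.array([z_vel])
    mean, P = kalman_predict_correct(
        state.mean, state.P, model.F, model.Q, H, R, zv, Bu=model.B * u_prev
    )
    return KalmanState(float(mean[0]), float(mean[1]), P)


def control_step(law: ControlLaw, x_est: float) -> float:
    """Proportional control step, saturated at the motor's per-cycle limit."""
    if not np.isfinite(x_est):
        raise ValueError("x_est must be finite")
    return float(np.clip(law.gain * (law.x_target - x_est), -law.u_max, law.u_max))
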