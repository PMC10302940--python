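"""SHOE (Stance Hypothesis Optimal Estimation) zero-velocity detector.

A generalized likelihood-ratio test over a sliding window of IMU samples: the
sensor is declared stationary when the windowed statistic

    T = (1/W) * sum_n [ ||a_n - g * abar/||abar||||^2 / sigma_a^2
                        + ||w_n||^2 / sigma_w^2 ]

falls below the threshold gamma.  The first term penalises specific force that
deviates from pure gravity along the window-mean direction; the second
penalises gyroscope energy.  Window decisions are OR-combined into a
per-sample mask (a sample is stationary if any accepted window covers it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateWindowError, InputError
from .synthgen import ImuTrace

__all__ = ["DetectorParams", "ZvMask", "shoe_statistic", "detect_zero_velocity"]

_NORM_FLOOR = 1e-9


@dataclass(frozen=True)
class DetectorParams:
    """SHOE detector tuning.

    W: window size (samples); sigma_a2 / sigma_w2: specific-force and
    angular-rate measurement variances; gamma: acceptance threshold (the
    dominant tuning parameter); g: gravity magnitude, m/s^2.
    """

    W: int = 5
    sigma_a2: float = 0.01
    sigma_w2: float = 0.001
    gamma: float = 300.0
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.W < 1:
            raise InputError(f"W must be >= 1, got {self.W}")
        if self.sigma_a2 <= 0 or self.sigma_w2 <= 0:
            raise InputError("measurement variances must be positive")
        if self.gamma <= 0:
            raise InputError("gamma must be positive")


@dataclass(frozen=True)
class ZvMask:
    """Per-sample stationarity flags plus the per-window statistic.

    ``statistic[k]`` is T for the window starting at sample k; ``flags[i]`` is
    True iff sample i lies in at least one window with T <= gamma.
    """

    flags: np.ndarray
    statistic: np.ndarray
    gamma: float
    W: int


def shoe_statistic(window_accel: np.ndarray, window_gyro: np.ndarray, params: DetectorParams) -> float:
    """Evaluate T on one window of W accelerometer and gyroscope samples."""
    a = np.asarray(window_accel, dtype=float)
    w = np.asarray(window_gyro, dtype=float)
    if a.shape != (params.W, 3) or w.shape != (params.W, 3):
        raise InputError(
            f"window shapes must be ({params.W}, 3); got accel {a.shape}, gyro {w.shape}"
        )
    abar = a.mean(axis=0)
    norm = np.linalg.norm(abar)
    if norm < _NORM_FLOOR:
        raise DegenerateWindowError("window mean specific force has (near-)zero norm")
    resid = a - params.g * abar / norm
    term_a = np.sum(resid**2, axis=1) / params.sigma_a2
    term_w = np.sum(w**2, axis=1) / params.sigma_w2
    return float(np.mean(term_a + term_w))


def detect_zero_velocity(trace: ImuTrace, params: DetectorParams) -> ZvMask:
    """Slide the SHOE window over the trace with stride 1 and build the mask."""
    n = trace.n
    W = params.W
    if n < W:
        raise InputError(f"trace length {n} shorter than window size {W}")

    aw = sliding_window_view(trace.accel, W, axis=0)  # (n-W+1, 3, W)
    gw = sliding_window_view(trace.gyro, W, axis=0)
    abar = aw.mean(axis=2)  # (n-W+1, 3)
    norms = np.linalg.norm(abar, axis=1)
    if np.any(norms < _NORM_FLOOR):
        raise DegenerateWindowError("a window's mean specific force has (near-)zero norm")
    unit = abar / norms[:, None]
    resid = aw - params.g * unit[:, :, None]
    term_a = np.sum(resid**2, axis=1) / params.sigma_a2  # (n-W+1, W)
    term_w = np.sum(gw**2, axis=1) / params.sigma_w2
    stat = np.mean(term_a + term_w, axis=1)

    accepted = stat <= params.gamma
    # OR-combine accepted windows into per-sample flags via a difference array
    delta = np.zeros(n + 1, dtype=int)
    starts = np.nonzero(accepted)[0]
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + W, -1)
    flags = np.cumsum(delta[:-1]) > 0
    return ZvMask(flags=flags, statistic=stat, gamma=params.gamma, W=W)
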