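"""Error-state extended Kalman filter with zero-velocity updates (ZUPT).

The nominal state (position p, velocity v, unit quaternion q, all SI) is
propagated by strapdown dead reckoning:

    a_k = R(q) a_body - (0, 0, g)          # specific force -> world accel
    p  <- p + v dt + 0.5 a_k dt^2
    v  <- v + a_k dt
    q  <- q (x) dq(w dt)                   # exact quaternion increment

A 9-dimensional error state (dp, dv, dtheta) rides alongside: dtheta is a
WORLD-frame small-angle attitude error, R_true = Exp([dtheta]x) R_nominal.
With this convention the first-order error transition is

    dp'     = dp + dv dt
    dv'     = dv - [R a_body]x dtheta dt
    dtheta' = dtheta

i.e. the transition matrix does not involve the gyro sample.  During detected
stance the pseudo-measurement z = 0 - v (velocity is zero) is fused with the
standard Kalman update; the estimated error is injected into the nominal
state (the quaternion by a small world-frame rotation) and then reset to zero.

Quaternions use the scalar-first (q0, q1, q2, q3) layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError, StateError
from .synthgen import ImuTrace
from .zvd import ZvMask

__all__ = [
    "NominalState",
    "ErrorState",
    "FilterParams",
    "FilterResult",
    "propagate",
    "propagate_error_covariance",
    "zupt_update",
    "run_filter",
    "initial_state_from_stationary",
    "quat_multiply",
    "quat_to_rotation_matrix",
    "quat_from_rotation_vector",
    "quat_yaw",
]

_QUAT_TOL = 1e-6


# ---------------------------------------------------------------------------
# quaternion algebra (scalar-first)


def quat_multiply(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w0, x0, y0, z0 = q
    w1, x1, y1, z1 = r
    return np.array(
        [
            w0 * w1 - x0 * x1 - y0 * y1 - z0 * z1,
            w0 * x1 + x0 * w1 + y0 * z1 - z0 * y1,
            w0 * y1 - x0 * z1 + y0 * w1 + z0 * x1,
            w0 * z1 + x0 * y1 - y0 * x1 + z0 * w1,
        ]
    )


def quat_to_rotation_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_rotation_vector(rv: np.ndarray) -> np.ndarray:
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        # second-order small-angle expansion keeps the norm at machine precision
        half = 0.5 * rv
        return np.concatenate([[1.0 - 0.125 * angle**2], half])
    axis = rv / angle
    return np.concatenate([[np.cos(0.5 * angle)], np.sin(0.5 * angle) * axis])


def quat_yaw(q: np.ndarray) -> float:
    """Heading about the world z axis, rad."""
    w, x, y, z = q
    return float(np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z)))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


# ---------------------------------------------------------------------------
# state containers


@dataclass(frozen=True)
class NominalState:
    """Position (m), velocity (m/s), attitude quaternion and timestamp (s)."""

    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    t: float = 0.0


@dataclass(frozen=True)
class ErrorState:
    """Zero-mean (dp, dv, dtheta) error with its 9x9 covariance."""

    cov: np.ndarray
    dp: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dv: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dtheta: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass(frozen=True)
class FilterParams:
    """Sampling period, gravity and noise tuning, all SI.

    accel_noise_std / gyro_noise_std feed the discrete process noise
    (Q_v = (sigma_a dt)^2 I, Q_theta = (sigma_g dt)^2 I); zupt_noise_std is the
    1-sigma of the zero-velocity pseudo-measurement.  init_* set the initial
    covariance diagonal.
    """

    dt: float = 0.01
    g: float = 9.81
    accel_noise_std: float = 0.05
    gyro_noise_std: float = 0.005
    zupt_noise_std: float = 0.01
    init_pos_std: float = 1e-4
    init_vel_std: float = 1e-3
    init_att_std: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InputError("dt must be positive")
        for name in ("accel_noise_std", "gyro_noise_std", "zupt_noise_std"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def initial_covariance(self) -> np.ndarray:
        d = np.concatenate(
            [
                np.full(3, self.init_pos_std**2),
                np.full(3, self.init_vel_std**2),
                np.full(3, self.init_att_std**2),
            ]
        )
        return np.diag(d)

    def process_noise(self) -> np.ndarray:
        q = np.zeros(9)
        q[3:6] = (self.accel_noise_std * self.dt) ** 2
        q[6:9] = (self.gyro_noise_std * self.dt) ** 2
        return np.diag(q)


@dataclass(frozen=True)
class FilterResult:
    """Per-sample nominal state estimates from run_filter."""

    t: np.ndarray
    p: np.ndarray  # (n, 3), m
    v: np.ndarray  # (n, 3), m/s
    q: np.ndarray  # (n, 4), scalar first
    zupt_applied: np.ndarray  # (n,) bool

    @property
    def n(self) -> int:
        return len(self.t)

    def yaw(self) -> np.ndarray:
        return np.array([quat_yaw(qk) for qk in self.q])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "px": self.p[:, 0],
                "py": self.p[:, 1],
                "pz": self.p[:, 2],
                "vx": self.v[:, 0],
                "vy": self.v[:, 1],
                "vz": self.v[:, 2],
                "q0": self.q[:, 0],
                "q1": self.q[:, 1],
                "q2": self.q[:, 2],
                "q3": self.q[:, 3],
                "zupt": self.zupt_applied.astype(int),
            }
        )


def _check_unit_quaternion(q: np.ndarray) -> None:
    if abs(np.linalg.norm(q) - 1.0) > _QUAT_TOL:
        raise StateError(f"quaternion norm {np.linalg.norm(q):.6g} deviates from 1")


def _check_psd(cov: np.ndarray) -> None:
    if cov.shape != (9, 9):
        raise StateError(f"covariance must be 9x9, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-9):
        raise StateError("covariance is not symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
        raise StateError("covariance is not positive semi-definite")


# ---------------------------------------------------------------------------
# filter operations


def propagate(state: NominalState, accel: np.ndarray, gyro: np.ndarray, params: FilterParams) -> NominalState:
    """One strapdown dead-reckoning step of the nominal state."""
    _check_unit_quaternion(state.q)
    dt = params.dt
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)

    R = quat_to_rotation_matrix(state.q)
    a_world = R @ accel - np.array([0.0, 0.0, params.g])
    p = state.p + state.v * dt + 0.5 * a_world * dt**2
    v = state.v + a_world * dt
    dq = quat_from_rotation_vector(gyro * dt)
    q = quat_multiply(state.q, dq)
    q = q / np.linalg.norm(q)
    return NominalState(p=p, v=v, q=q, t=state.t + dt)


def propagate_pair(
    state: NominalState,
    accel_prev: np.ndarray,
    gyro_prev: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    params: FilterParams,
) -> NominalState:
    """Two-sample strapdown step over [t_{k-1}, t_k].

    Same kinematic model as :func:`propagate`, but the angular rate and the
    world-frame acceleration are integrated trapezoidally across the interval
    (position keeps the zero-order-hold term of the single-sample step).  This
    removes the half-sample integration lag of the rectangle rule; it is the
    update :func:`run_filter` uses between consecutive IMU samples.
    """
    _check_unit_quaternion(state.q)
    dt = params.dt
    g_w = np.array([0.0, 0.0, params.g])

    R0 = quat_to_rotation_matrix(state.q)
    a0 = R0 @ np.asarray(accel_prev, dtype=float) - g_w
    dq = quat_from_rotation_vector(0.5 * (np.asarray(gyro_prev) + np.asarray(gyro)) * dt)
    q1 = quat_multiply(state.q, dq)
    q1 = q1 / np.linalg.norm(q1)
    a1 = quat_to_rotation_matrix(q1) @ np.asarray(accel, dtype=float) - g_w

    p = state.p + state.v * dt + 0.5 * a0 * dt**2
    v = state.v + 0.5 * (a0 + a1) * dt
    return NominalState(p=p, v=v, q=q1, t=state.t + dt)


def error_transition_matrix(state: NominalState, accel: np.ndarray, params: FilterParams) -> np.ndarray:
    """First-order transition of (dp, dv, dtheta) over one sample."""
    dt = params.dt
    R = quat_to_rotation_matrix(state.q)
    F = np.eye(9)
    F[0:3, 3:6] = np.eye(3) * dt
    F[3:6, 6:9] = -_skew(R @ np.asarray(accel, dtype=float)) * dt
    return F


def propagate_error_covariance(
    err: ErrorState, state: NominalState, accel: np.ndarray, params: FilterParams
) -> ErrorState:
    """cov <- F cov F^T + Q, symmetrized to fight round-off."""
    _check_psd(err.cov)
    F = error_transition_matrix(state, accel, params)
    cov = F @ err.cov @ F.T + params.process_noise()
    cov = 0.5 * (cov + cov.T)
    return ErrorState(cov=cov)


def zupt_update(
    state: NominalState, err: ErrorState, params: FilterParams
) -> tuple[NominalState, ErrorState]:
    """Fuse the zero-velocity pseudo-measurement and inject the error estimate.

    Measurement model: z = 0 - v with H selecting the velocity error block.
    Uses the Joseph-form covariance update; the posterior error mean is
    injected into the nominal state and reset to zero.
    """
    _check_psd(err.cov)
    P = err.cov
    H = np.zeros((3, 9))
    H[:, 3:6] = np.eye(3)
    Rm = params.zupt_noise_std**2 * np.eye(3)

    S = H @ P @ H.T + Rm
    try:
        K = np.linalg.solve(S.T, (P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular innovation covariance in ZUPT update") from exc
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e14:
        raise NumericalError("ill-conditioned innovation covariance in ZUPT update")

    z = -state.v
    dx = K @ z
    IKH = np.eye(9) - K @ H
    P_new = IKH @ P @ IKH.T + K @ Rm @ K.T
    P_new = 0.5 * (P_new + P_new.T)

    p = state.p + dx[0:3]
    v = state.v + dx[3:6]
    dq = quat_from_rotation_vector(dx[6:9])
    q = quat_multiply(dq, state.q)  # world-frame error: left multiply
    q = q / np.linalg.norm(q)
    new_state = NominalState(p=p, v=v, q=q, t=state.t)
    return new_state, ErrorState(cov=P_new)


def run_filter(
    trace: ImuTrace,
    mask: Optional[ZvMask],
    init: NominalState,
    params: FilterParams,
) -> FilterResult:
    """Run propagate / covariance / ZUPT over a whole trace.

    The state at index k is the estimate after processing IMU sample k; sample
    0 sets the initial state (with a ZUPT if flagged).  Deterministic given
    its inputs.
    """
    n = trace.n
    flags = mask.flags if mask is not None else np.zeros(n, dtype=bool)
    if len(flags) != n:
        raise InputError("mask and trace lengths differ")
    if n == 0:
        empty3 = np.zeros((0, 3))
        return FilterResult(
            t=np.zeros(0), p=empty3, v=empty3, q=np.zeros((0, 4)), zupt_applied=np.zeros(0, dtype=bool)
        )

    state = replace(init, t=float(trace.t[0]))
    err = ErrorState(cov=params.initial_covariance())

    p_out = np.empty((n, 3))
    v_out = np.empty((n, 3))
    q_out = np.empty((n, 4))
    applied = np.zeros(n, dtype=bool)

    for k in range(n):
        if k > 0:
            mid_accel = 0.5 * (trace.accel[k - 1] + trace.accel[k])
            err = propagate_error_covariance(err, state, mid_accel, params)
            state = propagate_pair(
                state, trace.accel[k - 1], trace.gyro[k - 1], trace.accel[k], trace.gyro[k], params
            )
        if flags[k]:
            state, err = zupt_update(state, err, params)
            applied[k] = True
        p_out[k] = state.p
        v_out[k] = state.v
        q_out[k] = state.q

    return FilterResult(t=trace.t.copy(), p=p_out, v=v_out, q=q_out, zupt_applied=applied)


def initial_state_from_stationary(
    trace: ImuTrace,
    n_samples: int = 50,
    p0: Sequence[float] = (0.0, 0.0, 0.0),
    yaw0: float = 0.0,
) -> NominalState:
    """Initialise attitude from the mean accelerometer of an initial stationary span.

    Roll and pitch come from aligning the measured specific-force direction
    with the world vertical; yaw is unobservable from gravity and is set to
    ``yaw0`` (0 unless external heading is available).
    """
    if trace.n < 1:
        raise InputError("empty trace")
    n_samples = min(n_samples, trace.n)
    mean_a = trace.accel[:n_samples].mean(axis=0)
    norm = np.linalg.norm(mean_a)
    if norm < 1e-9:
        raise InputError("mean specific force has zero norm; cannot level")
    u = mean_a / norm  # gravity direction in the body frame
    e3 = np.array([0.0, 0.0, 1.0])
    # rotation taking body gravity direction onto world z (tilt only)
    axis = np.cross(u, e3)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, e3))
    if s < 1e-12:
        q_tilt = np.array([1.0, 0.0, 0.0, 0.0]) if c > 0 else np.array([0.0, 1.0, 0.0, 0.0])
    else:
        angle = np.arctan2(s, c)
        q_tilt = quat_from_rotation_vector(axis / s * angle)
    q_yaw = quat_from_rotation_vector(np.array([0.0, 0.0, yaw0]))
    q = quat_multiply(q_yaw, q_tilt)
    q = q / np.linalg.norm(q)
    return NominalState(p=np.asarray(p0, dtype=float), v=np.zeros(3), q=q, t=float(trace.t[0]))
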