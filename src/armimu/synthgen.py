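"""Synthetic two-link planar arm trajectories and their IMU / camera observations.

The arm is modelled in the shoulder-anchored X-Y plane: the shoulder sits at the
origin, the upper arm (length ``l1``, cm) rotates about it by the shoulder angle
``theta1``, and the forearm (length ``l2``, cm) rotates about the elbow by the
relative flexion angle ``theta2``.  Forward kinematics::

    p_elbow = l1_eff * (cos th1, sin th1)
    p_wrist = p_elbow + l2 * (cos(th1 + th2), sin(th1 + th2))

``l1_eff`` carries an optional "muscle contraction" fluctuation — a seeded,
band-limited sinusoid-plus-noise whose peak magnitude equals the requested
amplitude — emulating the soft-tissue squeeze observed on the upper arm.

A wrist-mounted IMU is synthesised from the trajectory: the sensor frame is
aligned with the distal forearm segment (its yaw equals ``theta1 + theta2``),
the accelerometer reports specific force (a stationary level sensor reads
``(0, 0, +g)``), and the gyroscope reports the planar yaw rate about the body
z axis.  Marker pixel tracks for the shoulder, elbow and wrist come from a
single scalar pixel calibration (cm per pixel).

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ArmGeometry",
    "ArmTrajectory",
    "ImuTrace",
    "MarkerTrack",
    "MARKER_IDS",
    "simulate_arm",
    "imu_from_trajectory",
    "project_markers",
    "true_stationary_mask",
    "hold",
    "ramp",
    "sinusoid",
    "stance_swing_profile",
    "write_imu_csv",
    "read_imu_csv",
    "write_marker_csv",
    "read_marker_csv",
]

MARKER_IDS = ("shoulder", "elbow", "wrist")

AngleProfile = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the two-link arm, in centimetres.

    l1: shoulder -> elbow centre; l2: elbow -> wrist centre.
    """

    l1: float
    l2: float

    def __post_init__(self) -> None:
        if not (self.l1 > 0 and self.l2 > 0):
            raise InputError(f"segment lengths must be positive, got l1={self.l1}, l2={self.l2}")


@dataclass(frozen=True)
class ArmTrajectory:
    """Ground-truth planar arm motion on a uniform time grid.

    Positions are in cm in the shoulder-origin X-Y frame; angles in rad.
    ``l1_effective`` is l1 plus the contraction fluctuation, so that
    ``|p_elbow| == l1_effective`` and ``|p_wrist - p_elbow| == l2`` exactly.
    """

    t: np.ndarray
    shoulder_angle: np.ndarray
    elbow_angle: np.ndarray
    p_elbow: np.ndarray
    p_wrist: np.ndarray
    l1_effective: np.ndarray
    geometry: ArmGeometry

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def yaw(self) -> np.ndarray:
        """Planar heading of the forearm segment == sensor yaw, rad."""
        return self.shoulder_angle + self.elbow_angle


@dataclass(frozen=True)
class ImuTrace:
    """Uniformly sampled wrist IMU output: specific force (m/s^2) and angular rate (rad/s)."""

    t: np.ndarray
    accel: np.ndarray  # (n, 3), sensor frame
    gyro: np.ndarray  # (n, 3), sensor frame
    bias_a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bias_g: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_std_a: float = 0.0
    noise_std_g: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.accel) == len(self.gyro)):
            raise InputError("t, accel and gyro must have equal lengths")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class MarkerTrack:
    """Planar marker coordinates in pixels, with a scalar cm-per-pixel calibration.

    ``pixels`` has shape (n_samples, n_markers, 2); marker order follows
    ``marker_ids`` (shoulder, elbow, wrist by default).
    """

    t: np.ndarray
    pixels: np.ndarray
    cm_per_pixel: float
    marker_ids: tuple = MARKER_IDS

    def __post_init__(self) -> None:
        if not self.cm_per_pixel > 0:
            raise InputError(f"cm_per_pixel must be positive, got {self.cm_per_pixel}")

    def to_cm(self) -> np.ndarray:
        return self.pixels * self.cm_per_pixel


# ---------------------------------------------------------------------------
# angle profiles


def hold(value: float) -> AngleProfile:
    """Constant angle profile."""
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


def ramp(start: float, stop: float, duration: float) -> AngleProfile:
    """Linear ramp from start to stop over [0, duration], clamped after."""

    def f(t):
        t = np.asarray(t, dtype=float)
        return start + (stop - start) * np.clip(t / duration, 0.0, 1.0)

    return f


def sinusoid(amplitude: float, freq_hz: float, offset: float = 0.0, phase: float = 0.0) -> AngleProfile:
    def f(t):
        t = np.asarray(t, dtype=float)
        return offset + amplitude * np.sin(2.0 * np.pi * freq_hz * t + phase)

    return f


def _smoothstep5(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2 at both ends, so synthesised accelerations are continuous."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (10.0 + x * (-15.0 + 6.0 * x))


def stance_swing_profile(
    lo: float,
    hi: float,
    period: float,
    stance_fraction: float = 0.4,
) -> AngleProfile:
    """Alternating hold/move profile emulating stance and swing phases.

    Each cycle of length ``period`` holds the current angle for
    ``stance_fraction * period`` seconds, then sweeps smoothly (quintic ease,
    zero end velocity and acceleration) to the opposite extreme.  Even cycles
    go lo -> hi, odd cycles hi -> lo.
    """
    if not 0.0 < stance_fraction < 1.0:
        raise InputError("stance_fraction must lie in (0, 1)")
    if period <= 0:
        raise InputError("period must be positive")

    def f(t):
        t = np.asarray(t, dtype=float)
        cycle = np.floor(t / period).astype(int)
        u = t / period - cycle
        start = np.where(cycle % 2 == 0, lo, hi)
        end = np.where(cycle % 2 == 0, hi, lo)
        s = np.clip((u - stance_fraction) / (1.0 - stance_fraction), 0.0, 1.0)
        return start + (end - start) * _smoothstep5(s)

    return f


def stance_mask_for_profile(t: np.ndarray, period: float, stance_fraction: float) -> np.ndarray:
    """Boolean mask of the samples inside the hold phase of stance_swing_profile."""
    u = np.asarray(t, dtype=float) / period
    return (u - np.floor(u)) < stance_fraction


# ---------------------------------------------------------------------------
# generators


def _contraction_series(n: int, dt: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited sinusoid-plus-noise fluctuation of the upper-arm length.

    A squeeze-rate sinusoid whose cycle-to-cycle height is modulated by
    low-passed noise (+-8%), so individual peak deviations scatter around
    ``amplitude`` — the peak effect size, cm.
    """
    if amplitude == 0.0 or n == 0:
        return np.zeros(n)
    t = np.arange(n) * dt
    freq = 1.2  # Hz, hand-squeeze rate
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = np.sin(2.0 * np.pi * freq * t + phase)
    # low-passed white noise modulates the envelope
    noise = rng.standard_normal(n)
    win = max(3, int(round(0.25 / dt)) | 1)
    kernel = np.hanning(win)
    kernel /= kernel.sum()
    smooth = np.convolve(noise, kernel, mode="same")
    peak = np.max(np.abs(smooth))
    envelope = 1.0 + (0.08 * smooth / peak if peak > 0 else 0.0)
    return amplitude * carrier * envelope


def simulate_arm(
    geometry: ArmGeometry,
    angle_profiles: Sequence[AngleProfile],
    duration: float,
    dt: float = 0.01,
    contraction_amplitude: float = 0.0,
    seed: int = 0,
) -> ArmTrajectory:
    """Forward-kinematics simulation of the planar two-link arm.

    Parameters
    ----------
    geometry : ArmGeometry
        Segment lengths in cm.
    angle_profiles : (shoulder_profile, elbow_profile)
        Callables mapping a time array (s) to angle arrays (rad).
    duration, dt : float
        Trace length and sampling period, s.
    contraction_amplitude : float
        Peak magnitude (cm) of the l1 fluctuation; 0 disables it.
    seed : int
        Seeds the fluctuation; identical seeds give identical output.
    """
    if dt <= 0:
        raise InputError(f"dt must be positive, got {dt}")
    if duration < dt:
        raise InputError(f"duration must be >= dt, got {duration} < {dt}")
    if contraction_amplitude < 0:
        raise InputError("contraction_amplitude must be >= 0")

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    shoulder_fn, elbow_fn = angle_profiles
    th1 = np.asarray(shoulder_fn(t), dtype=float)
    th2 = np.asarray(elbow_fn(t), dtype=float)

    rng = np.random.default_rng(seed)
    l1_eff = geometry.l1 + _contraction_series(n, dt, contraction_amplitude, rng)

    p_elbow = np.column_stack([l1_eff * np.cos(th1), l1_eff * np.sin(th1)])
    heading = th1 + th2
    p_wrist = p_elbow + geometry.l2 * np.column_stack([np.cos(heading), np.sin(heading)])

    return ArmTrajectory(
        t=t,
        shoulder_angle=th1,
        elbow_angle=th2,
        p_elbow=p_elbow,
        p_wrist=p_wrist,
        l1_effective=l1_eff,
        geometry=geometry,
    )


def _central_second_difference(pos: np.ndarray, dt: float) -> np.ndarray:
    """Per-axis second differences; edge samples replicate their neighbours."""
    acc = np.empty_like(pos)
    acc[1:-1] = (pos[2:] - 2.0 * pos[1:-1] + pos[:-2]) / dt**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def imu_from_trajectory(
    traj: ArmTrajectory,
    gravity: float = 9.81,
    bias_a: Sequence[float] = (0.0, 0.0, 0.0),
    bias_g: Sequence[float] = (0.0, 0.0, 0.0),
    noise_std_a: float = 0.0,
    noise_std_g: float = 0.0,
    seed: int = 0,
) -> ImuTrace:
    """Synthesise the wrist IMU output implied by a trajectory.

    The sensor frame is attached to the distal forearm: its x axis points
    elbow -> wrist, z is the world vertical, so the sensor-to-world rotation is
    a pure yaw by ``traj.yaw``.  Specific force follows the reaction
    convention: a stationary level sensor reads ``(0, 0, +gravity)``.
    World acceleration comes from central second differences of the wrist
    position (converted cm -> m); constant biases and white Gaussian noise are
    added last.
    """
    if gravity <= 0:
        raise InputError("gravity must be positive")
    if noise_std_a < 0 or noise_std_g < 0:
        raise InputError("noise standard deviations must be >= 0")
    if traj.n < 3:
        raise InputError("trajectory must have at least 3 samples for second differences")

    dt = traj.dt
    pos_m = np.column_stack([traj.p_wrist / 100.0, np.zeros(traj.n)])  # cm -> m, planar
    acc_world = _central_second_difference(pos_m, dt)
    # specific force f_b = R^T (a_world - g_world), g_world = (0,0,-g)
    f_world = acc_world + np.array([0.0, 0.0, gravity])

    yaw = traj.yaw
    c, s = np.cos(yaw), np.sin(yaw)
    # rotate world -> sensor (R^T for a yaw rotation)
    fx = c * f_world[:, 0] + s * f_world[:, 1]
    fy = -s * f_world[:, 0] + c * f_world[:, 1]
    accel = np.column_stack([fx, fy, f_world[:, 2]])

    yaw_rate = np.gradient(yaw, dt)
    gyro = np.column_stack([np.zeros(traj.n), np.zeros(traj.n), yaw_rate])

    bias_a = np.asarray(bias_a, dtype=float)
    bias_g = np.asarray(bias_g, dtype=float)
    rng = np.random.default_rng(seed)
    accel = accel + bias_a + noise_std_a * rng.standard_normal((traj.n, 3))
    gyro = gyro + bias_g + noise_std_g * rng.standard_normal((traj.n, 3))

    return ImuTrace(
        t=traj.t.copy(),
        accel=accel,
        gyro=gyro,
        bias_a=bias_a,
        bias_g=bias_g,
        noise_std_a=noise_std_a,
        noise_std_g=noise_std_g,
    )


def project_markers(
    traj: ArmTrajectory,
    cm_per_pixel: float = 0.042,
    jitter_px: float = 0.0,
    seed: int = 0,
) -> MarkerTrack:
    """Project shoulder/elbow/wrist onto the camera pixel grid.

    pixels = cm coordinates / cm_per_pixel + N(0, jitter_px) per axis.
    """
    if cm_per_pixel <= 0:
        raise InputError("cm_per_pixel must be positive")
    if jitter_px < 0:
        raise InputError("jitter_px must be >= 0")

    shoulder = np.zeros((traj.n, 2))
    cm = np.stack([shoulder, traj.p_elbow, traj.p_wrist], axis=1)  # (n, 3, 2)
    px = cm / cm_per_pixel
    if jitter_px > 0:
        rng = np.random.default_rng(seed)
        px = px + jitter_px * rng.standard_normal(px.shape)
    return MarkerTrack(t=traj.t.copy(), pixels=px, cm_per_pixel=cm_per_pixel)


def true_stationary_mask(traj: ArmTrajectory, speed_tol: float = 0.05, rate_tol: float = 1e-3) -> np.ndarray:
    """Ground-truth per-sample stationarity of the wrist sensor.

    A sample is stationary when the wrist speed (cm/s, central differences)
    and the sensor yaw rate (rad/s) both fall below their tolerances.
    """
    dt = traj.dt
    vel = np.gradient(traj.p_wrist, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    rate = np.abs(np.gradient(traj.yaw, dt))
    return (speed < speed_tol) & (rate < rate_tol)


# ---------------------------------------------------------------------------
# CSV interchange


def write_imu_csv(trace: ImuTrace, path) -> None:
    df = pd.DataFrame(
        {
            "t": trace.t,
            "ax": trace.accel[:, 0],
            "ay": trace.accel[:, 1],
            "az": trace.accel[:, 2],
            "gx": trace.gyro[:, 0],
            "gy": trace.gyro[:, 1],
            "gz": trace.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_imu_csv(path) -> ImuTrace:
    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"IMU CSV missing columns: {missing}")
    return ImuTrace(
        t=df["t"].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )


def write_trajectory_csv(traj: ArmTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "t": traj.t,
            "shoulder_angle": traj.shoulder_angle,
            "elbow_angle": traj.elbow_angle,
            "elbow_x": traj.p_elbow[:, 0],
            "elbow_y": traj.p_elbow[:, 1],
            "wrist_x": traj.p_wrist[:, 0],
            "wrist_y": traj.p_wrist[:, 1],
            "l1_effective": traj.l1_effective,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path, geometry: ArmGeometry) -> ArmTrajectory:
    df = pd.read_csv(path)
    return ArmTrajectory(
        t=df["t"].to_numpy(),
        shoulder_angle=df["shoulder_angle"].to_numpy(),
        elbow_angle=df["elbow_angle"].to_numpy(),
        p_elbow=df[["elbow_x", "elbow_y"]].to_numpy(),
        p_wrist=df[["wrist_x", "wrist_y"]].to_numpy(),
        l1_effective=df["l1_effective"].to_numpy(),
        geometry=geometry,
    )


def write_marker_csv(track: MarkerTrack, path) -> None:
    rows = []
    for j, mid in enumerate(track.marker_ids):
        rows.append(
            pd.DataFrame(
                {
                    "t": track.t,
                    "marker_id": mid,
                    "px": track.pixels[:, j, 0],
                    "py": track.pixels[:, j, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_marker_csv(path, cm_per_pixel: float) -> MarkerTrack:
    df = pd.read_csv(path)
    ids = tuple(dict.fromkeys(df["marker_id"]))
    t = df[df["marker_id"] == ids[0]]["t"].to_numpy()
    px = np.stack(
        [df[df["marker_id"] == mid][["px", "py"]].to_numpy() for mid in ids],
        axis=1,
    )
    return MarkerTrack(t=t, pixels=px, cm_per_pixel=cm_per_pixel, marker_ids=ids)
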