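"""Run configuration: one YAML-loadable object holding every stage's parameters.

All randomness in a run flows from the single ``seed``; per-stage integer
seeds are derived from it deterministically.  ``validate()`` constructs the
per-module parameter objects up front, so a bad value (e.g. a non-positive
segment length) is rejected before any stage executes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import InputError
from .synthgen import ArmGeometry
from .zvd import DetectorParams
from .ekf import FilterParams

__all__ = ["MotionConfig", "SynthConfig", "RunConfig", "load_config"]


@dataclass
class MotionConfig:
    """Stance/swing sweep bounds for one joint angle, rad."""

    lo: float = 0.3
    hi: float = 1.0


@dataclass
class SynthConfig:
    """Synthetic study conditions: arm motion, IMU imperfections, camera scale."""

    duration: float = 12.0
    dt: float = 0.01
    period: float = 2.5
    stance_fraction: float = 0.4
    shoulder: MotionConfig = field(default_factory=lambda: MotionConfig(0.35, 1.1))
    elbow: MotionConfig = field(default_factory=lambda: MotionConfig(0.3, 1.0))
    contraction_amplitude: float = 0.5  # cm
    gravity: float = 9.81
    bias_a: tuple = (0.02, 0.0, 0.0)  # m/s^2
    bias_g: tuple = (0.002, 0.0, 0.0)  # rad/s
    noise_std_a: float = 0.05  # m/s^2
    noise_std_g: float = 0.005  # rad/s
    cm_per_pixel: float = 0.042
    jitter_px: float = 1.0


@dataclass
class ZvdConfig:
    W: int = 5
    sigma_a2: float = 2.5e-3  # matches noise_std_a^2
    sigma_w2: float = 2.5e-5  # matches noise_std_g^2
    gamma: float = 300.0
    g: float = 9.81


@dataclass
class EkfConfig:
    accel_noise_std: float = 0.05
    gyro_noise_std: float = 0.005
    zupt_noise_std: float = 0.01
    init_pos_std: float = 1e-4
    init_vel_std: float = 1e-3
    init_att_std: float = 1e-3


@dataclass
class RunConfig:
    """Everything a pipeline run needs, seeded once."""

    seed: int = 0
    l1: float = 30.0  # cm
    l2: float = 25.0  # cm
    synth: SynthConfig = field(default_factory=SynthConfig)
    zvd: ZvdConfig = field(default_factory=ZvdConfig)
    ekf: EkfConfig = field(default_factory=EkfConfig)

    def geometry(self) -> ArmGeometry:
        return ArmGeometry(l1=self.l1, l2=self.l2)

    def detector_params(self) -> DetectorParams:
        z = self.zvd
        return DetectorParams(W=z.W, sigma_a2=z.sigma_a2, sigma_w2=z.sigma_w2, gamma=z.gamma, g=z.g)

    def filter_params(self) -> FilterParams:
        e = self.ekf
        return FilterParams(
            dt=self.synth.dt,
            g=self.synth.gravity,
            accel_noise_std=e.accel_noise_std,
            gyro_noise_std=e.gyro_noise_std,
            zupt_noise_std=e.zupt_noise_std,
            init_pos_std=e.init_pos_std,
            init_vel_std=e.init_vel_std,
            init_att_std=e.init_att_std,
        )

    def validate(self) -> None:
        """Construct every stage's parameter object; raises InputError on bad values."""
        self.geometry()
        self.detector_params()
        self.filter_params()
        s = self.synth
        if s.duration < s.dt or s.dt <= 0:
            raise InputError("synth duration/dt invalid")
        if s.contraction_amplitude < 0 or s.jitter_px < 0:
            raise InputError("synth noise amplitudes must be >= 0")
        if not 0 < s.stance_fraction < 1:
            raise InputError("stance_fraction must lie in (0, 1)")

    def stage_seeds(self) -> dict:
        """Derive independent per-stage integer seeds (< 2^31) from the run seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("trajectory", "imu", "markers")
        states = [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(len(names))]
        return dict(zip(names, states))


def _merge_dataclass(obj, data: dict):
    for f in dataclasses.fields(obj):
        if f.name not in data:
            continue
        value = data[f.name]
        current = getattr(obj, f.name)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge_dataclass(current, value)
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, f.name, tuple(value))
        else:
            setattr(obj, f.name, value)
    unknown = set(data) - {f.name for f in dataclasses.fields(obj)}
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return obj


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _merge_dataclass(cfg, data)
    if overrides:
        _merge_dataclass(cfg, overrides)
    return cfg
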