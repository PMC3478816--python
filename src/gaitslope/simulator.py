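"""Synthetic sagittal-plane gait generator with ground truth.

The stance leg behaves like an inverted pendulum pivoting about the
foot; mid-stance is the instant when the shank passes near vertical with
near-zero angular speed, and the sensor point is momentarily at rest.
The generator builds a smooth periodic shank-angle trajectory and a
sensor-point trajectory advancing along the inclined walking line, with
exact stationary points (zero linear velocity *and* acceleration, and a
lower-lobe angular-speed maximum) at every mid-stance instant.  Sensor
channels are synthesized by rotating the true specific force
(global acceleration plus gravity) into the shank frame, optionally with
additive Gaussian noise and a constant gyro bias.

With one stride per period of duration T and phase u = t/T (mid-stance
at integer u), the construction is

    ω(t)      = (A/T) · [cos 4πu − (1+η) cos 2πu]           (gyro truth)
    θ(t)      = θ_MS + A · [sin 4πu/4π − (1+η) sin 2πu/2π]
    x(t)      = L · [u − sin 2πu / 2π],   y(t) = slope · x(t)

η ≪ 1 leaves a small negative angular speed at mid-stance so the lower
lobe has a well-defined interior maximum there; the position profile has
x' = x'' = 0 at integer u, so the stationarity assumptions hold exactly
and each stride advances by exactly one stride length L with rise
slope·L — the true per-stride slope is the scenario slope by
construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConstructionError, ValidationError
from .io import IMURecording

__all__ = [
    "GaitScenario",
    "GroundTruth",
    "simulate_recording",
    "inject_assumption_violation",
]

#: fraction of a stride by which ω undershoots zero at mid-stance
_MS_LOBE_DEPTH = 0.02
#: shank-angle waveform amplitude (rad); excursion ≈ ±0.21·_THETA_AMP
_THETA_AMP = 1.2

#: stationarity tolerances reported with (and enforced on) the ground truth
TOL_OMEGA_MS = 0.05   # rad/s
TOL_V_MS = 1e-9       # m/s
TOL_A_MS = 1e-9       # m/s²


@dataclass
class GaitScenario:
    """Parameters of one simulated treadmill walk.

    Defaults mirror a typical protocol: 4 km/h (1.11 m/s) belt speed,
    100 Hz sampling, sensor mid-shank (~0.25 m above the foot pivot).
    ``theta_ms_true`` is the shank tilt at mid-stance; by default it
    scales with the surface slope (``tilt_gain`` · slope), since on an
    incline the stance shank is not aligned with gravity at mid-stance.
    Noise defaults (accel 0.1 m/s², gyro 0.01 rad/s) produce per-stride
    slope scatter of roughly 0.04 and are generator choices, not
    measured device characteristics.
    """

    slope: float = 0.0            #: per-unit rise over run
    speed: float = 1.11           #: m/s
    stride_time: float = 1.1      #: s
    n_strides: int = 30
    r: float = 0.25               #: sensor height above the pivot, m
    fs: float = 100.0             #: Hz
    theta_ms_true: float | None = None  #: rad; None → tilt_gain · slope
    tilt_gain: float = 1.0
    accel_noise_sd: float = 0.1   #: m/s²
    gyro_noise_sd: float = 0.01   #: rad/s
    gyro_bias: float = 0.0        #: rad/s, constant
    residual_omega_ms: float = 0.0   #: rad/s left at mid-stance (violation)
    residual_accel_ms: float = 0.0   #: m/s² left at mid-stance (violation)
    g: float = 9.8                #: m/s²
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 3:
            raise ValidationError("n_strides must be at least 3")
        if self.stride_time <= 0 or self.speed <= 0 or self.fs <= 0:
            raise ValidationError("speed, stride_time and fs must be positive")
        if self.fs <= 2.0 * 2.0 / self.stride_time:
            raise ValidationError(
                "fs must exceed twice the dominant gait frequency"
            )

    @property
    def stride_length(self) -> float:
        return self.speed * self.stride_time

    @property
    def theta_ms(self) -> float:
        if self.theta_ms_true is not None:
            return self.theta_ms_true
        return self.tilt_gain * self.slope


@dataclass
class GroundTruth:
    """Analytic truth accompanying a simulated recording."""

    mid_stance_times: np.ndarray   #: s, one per mid-stance instant
    theta_true: np.ndarray         #: rad, per sample
    a_v_true: np.ndarray           #: m/s², per sample
    a_ap_true: np.ndarray          #: m/s², per sample
    slope: float
    S_v: np.ndarray                #: m, per stride
    S_ap: np.ndarray               #: m, per stride
    tolerances: dict = field(default_factory=dict)


def simulate_recording(scn: GaitScenario) -> tuple[IMURecording, GroundTruth]:
    """Generate a shank-frame IMU recording and its ground truth.

    The recording is padded by one and a half strides on each side so
    every reported mid-stance instant lies strictly between two interior
    swing peaks and is detectable; ``scn.n_strides`` complete strides
    lie between the ``n_strides + 1`` mid-stance instants in the truth.
    """
    T, L, N = scn.stride_time, scn.stride_length, scn.n_strides
    dt = 1.0 / scn.fs
    t = np.arange(0.0, (N + 3) * T + 0.5 * dt, dt)
    # phase u: mid-stance at integer u; swing peaks at half-integers
    u = t / T - 0.5
    eta = _MS_LOBE_DEPTH
    A = _THETA_AMP

    omega_true = (A / T) * (np.cos(4 * np.pi * u) - (1 + eta) * np.cos(2 * np.pi * u))
    theta_true = scn.theta_ms + A * (
        np.sin(4 * np.pi * u) / (4 * np.pi)
        - (1 + eta) * np.sin(2 * np.pi * u) / (2 * np.pi)
    )
    # sensor-point acceleration along the inclined line
    a_ap_true = (L / T**2) * 2 * np.pi * np.sin(2 * np.pi * u)
    a_v_true = scn.slope * a_ap_true

    # skip the first and last padded cycles: detection discards them
    ms_times = (np.arange(N + 1) + 1.5) * T
    _check_stationarity(scn, T, L, A, eta)

    # violations: zero-mean periodic perturbations peaking at mid-stance.
    # The angular-speed residual is negative there so the lower lobe stays
    # a lobe (its |value| at mid-stance is the requested magnitude).
    delta_omega = -scn.residual_omega_ms * np.cos(2 * np.pi * u)
    delta_accel = scn.residual_accel_ms * np.cos(2 * np.pi * u)

    a_ap_sig = a_ap_true + delta_accel
    c, s = np.cos(theta_true), np.sin(theta_true)
    a_n = (a_v_true + scn.g) * c - a_ap_sig * s
    a_t = (a_v_true + scn.g) * s + a_ap_sig * c
    # pendulum centripetal term of the residual angular speed (Eq. a_n = ω²r)
    a_n = a_n + scn.r * delta_omega**2
    omega_sig = omega_true + delta_omega + scn.gyro_bias

    rng = np.random.default_rng(scn.seed)
    if scn.accel_noise_sd > 0:
        a_n = a_n + rng.normal(0.0, scn.accel_noise_sd, a_n.size)
        a_t = a_t + rng.normal(0.0, scn.accel_noise_sd, a_t.size)
    if scn.gyro_noise_sd > 0:
        omega_sig = omega_sig + rng.normal(0.0, scn.gyro_noise_sd, omega_sig.size)

    rec = IMURecording(
        time=t, a_n=a_n, a_t=a_t, omega=omega_sig, fs=scn.fs,
        meta={"slope": scn.slope, "theta_ms_true": scn.theta_ms},
    )
    truth = GroundTruth(
        mid_stance_times=ms_times,
        theta_true=theta_true,
        a_v_true=a_v_true,
        a_ap_true=a_ap_true,
        slope=scn.slope,
        S_v=np.full(N, scn.slope * L),
        S_ap=np.full(N, L),
        tolerances={
            "omega_ms": eta * A / T,
            "v_ms": 0.0,
            "a_ms": 0.0,
            "tol_omega": TOL_OMEGA_MS,
            "tol_v": TOL_V_MS,
            "tol_a": TOL_A_MS,
        },
    )
    return rec, truth


def _check_stationarity(
    scn: GaitScenario, T: float, L: float, A: float, eta: float
) -> None:
    """Verify the clean construction meets the mid-stance tolerances."""
    omega_ms = eta * A / T
    if omega_ms > TOL_OMEGA_MS:
        raise ConstructionError(
            f"angular speed at mid-stance {omega_ms:.3g} rad/s exceeds "
            f"tolerance {TOL_OMEGA_MS} rad/s (stride_time too short)"
        )
    # velocity/acceleration vanish analytically at integer phase; sampling
    # must land close enough to a mid-stance instant to realize that
    offset = _sample_offset(T, scn.fs)
    v_ms = L / T * (1 - np.cos(2 * np.pi * offset))
    if v_ms > 1e-3:
        raise ConstructionError(
            f"sampling grid misses mid-stance instants by {offset:.3g} "
            f"strides; residual velocity {v_ms:.3g} m/s"
        )


def _sample_offset(T: float, fs: float) -> float:
    """Distance (in strides) from a mid-stance instant to its nearest sample."""
    samples_per_stride = T * fs
    frac = (0.5 * samples_per_stride) % 1.0
    return min(frac, 1.0 - frac) / samples_per_stride


_VIOLATION_KINDS = ("residual_omega_ms", "residual_accel_ms", "gyro_bias")


def inject_assumption_violation(
    scn: GaitScenario, kind: str, magnitude: float
) -> GaitScenario:
    """Return a scenario with one mid-stance assumption relaxed.

    ``kind`` is one of ``residual_omega_ms`` (rad/s of angular speed left
    at mid-stance; corrupts the tilt reading through the pendulum's ω²r
    centripetal term), ``residual_accel_ms`` (m/s² of linear acceleration
    left at mid-stance) or ``gyro_bias`` (constant rad/s added to the
    gyro channel).
    """
    if kind not in _VIOLATION_KINDS:
        raise ValueError(
            f"unknown violation kind {kind!r}; expected one of {_VIOLATION_KINDS}"
        )
    return dataclasses.replace(scn, **{kind: magnitude})
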