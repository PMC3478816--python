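"""Per-stride strapdown slope estimation.

The core algorithm: at each mid-stance event the accelerometer, assumed
to sense gravity only, acts as a tilt sensor giving the initial shank
inclination θ_MS = arctan(a_t/a_n).  The gyro is integrated from that
initial condition to obtain θ(t) over the stride, the sensor-frame
specific forces are rotated into the global frame (and gravity removed),
and double integration from zero initial velocity yields the vertical
and antero-posterior displacements S_v, S_ap of the stride.  The
walking-surface slope is their ratio Θ = S_v / S_ap (per-unit rise over
run).  Re-initializing at every stride bounds integration drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .errors import OrientationError, ValidationError
from .io import IMURecording, PipelineConfig
from .preprocessing import detect_mid_stance, segment_strides, zero_phase_lowpass

__all__ = [
    "StrideKinematics",
    "SlopeSeries",
    "tilt_at_mid_stance",
    "integrate_orientation",
    "project_to_global",
    "integrate_displacements",
    "stride_slope",
    "estimate_slopes",
]

logger = logging.getLogger(__name__)


@dataclass
class StrideKinematics:
    """Kinematic quantities of one stride, sampled over its window."""

    theta: np.ndarray      #: sensor inclination vs. global vertical, rad
    theta_ms: float        #: initial tilt at the stride's mid-stance, rad
    a_v: np.ndarray        #: global vertical acceleration, m/s²
    a_ap: np.ndarray       #: global antero-posterior acceleration, m/s²
    V_v: np.ndarray        #: vertical velocity (zero at stride start), m/s
    V_ap: np.ndarray       #: antero-posterior velocity, m/s
    S_v: float             #: vertical displacement over the stride, m
    S_ap: float            #: antero-posterior displacement, m

    def __post_init__(self) -> None:
        if self.theta[0] != self.theta_ms:
            raise ValidationError("theta[0] must equal theta_ms")
        if self.V_v[0] != 0.0 or self.V_ap[0] != 0.0:
            raise ValidationError("initial velocities must be zero")


@dataclass
class SlopeSeries:
    """Per-stride slope estimates with optional ground truth.

    ``slopes`` holds Θ_i as per-unit rise-over-run (the tangent of the
    surface inclination angle); ``label`` tracks the processing stage
    (raw / calibrated / smoothed).
    """

    slopes: np.ndarray
    stride_times: np.ndarray
    truth: np.ndarray | None = None
    label: str = "raw"
    flags: np.ndarray | None = None      #: True marks a degenerate stride
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.stride_times = np.asarray(self.stride_times, dtype=float)
        if self.slopes.shape != self.stride_times.shape:
            raise ValidationError("slopes and stride_times must match in length")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.slopes.shape:
                raise ValidationError("truth must match slopes in length")
        if self.flags is None:
            self.flags = np.zeros(self.slopes.shape, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.slopes.shape:
                raise ValidationError("flags must match slopes in length")

    @property
    def n_strides(self) -> int:
        return self.slopes.size

    def valid(self) -> "SlopeSeries":
        """Return a copy restricted to non-degenerate strides."""
        keep = ~self.flags
        return SlopeSeries(
            slopes=self.slopes[keep],
            stride_times=self.stride_times[keep],
            truth=None if self.truth is None else self.truth[keep],
            label=self.label,
            meta=dict(self.meta),
        )


def tilt_at_mid_stance(a_n_ms: float, a_t_ms: float) -> float:
    """Sensor inclination from vertical at mid-stance, in radians.

    Assumes the accelerometer senses gravity only at that instant, so the
    tilt is arctan(a_t / a_n).  Requires the shank roughly upright
    (a_n > 0); a non-positive normal channel means the gravity-only
    assumption cannot hold.
    """
    if a_n_ms <= 0:
        raise OrientationError(
            f"normal acceleration {a_n_ms:.3f} m/s² at mid-stance is not "
            "positive; sensor is not roughly upright"
        )
    return float(np.arctan2(a_t_ms, a_n_ms))


def integrate_orientation(
    omega_window: np.ndarray, fs: float, theta_ms: float
) -> np.ndarray:
    """θ(t) over a stride: initial tilt plus the cumulative trapezoidal
    integral of the angular speed.  θ[0] equals ``theta_ms`` exactly."""
    w = np.asarray(omega_window, dtype=float)
    return theta_ms + cumulative_trapezoid(w, dx=1.0 / fs, initial=0.0)


def project_to_global(
    a_n: np.ndarray, a_t: np.ndarray, theta: np.ndarray, g: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate sensor-frame specific forces into the global frame and
    remove gravity:

        a_v  =  a_n cos θ + a_t sin θ − g
        a_ap = −a_n sin θ + a_t cos θ
    """
    a_n = np.asarray(a_n, dtype=float)
    a_t = np.asarray(a_t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (a_n.shape == a_t.shape == theta.shape):
        raise ValidationError("a_n, a_t and theta must have equal lengths")
    c, s = np.cos(theta), np.sin(theta)
    a_v = a_n * c + a_t * s - g
    a_ap = -a_n * s + a_t * c
    return a_v, a_ap


def integrate_displacements(
    a_v: np.ndarray, a_ap: np.ndarray, fs: float
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Displacements over a stride from zero initial velocity.

    Velocities are the cumulative trapezoidal integrals of the global
    accelerations; S_v and S_ap are the trapezoidal integrals of the
    velocities over the whole window.
    """
    dt = 1.0 / fs
    V_v = cumulative_trapezoid(np.asarray(a_v, float), dx=dt, initial=0.0)
    V_ap = cumulative_trapezoid(np.asarray(a_ap, float), dx=dt, initial=0.0)
    S_v = float(trapezoid(V_v, dx=dt))
    S_ap = float(trapezoid(V_ap, dx=dt))
    return S_v, S_ap, V_v, V_ap


def stride_slope(S_v: float, S_ap: float, epsilon: float = 0.05) -> tuple[float, bool]:
    """Per-unit slope Θ = S_v / S_ap of one stride.

    Returns ``(slope, degenerate)``; a stride with |S_ap| ≤ ``epsilon``
    metres shows no usable forward progression and is flagged (slope is
    still reported, NaN if S_ap is exactly zero) rather than dropped.
    """
    degenerate = abs(S_ap) <= epsilon
    if S_ap == 0.0:
        return float("nan"), True
    return S_v / S_ap, degenerate


def _stride_kinematics(
    window: dict, fs: float, cfg: PipelineConfig
) -> StrideKinematics:
    a_n, a_t, omega = window["a_n"], window["a_t"], window["omega"]
    if cfg.use_tilt_correction:
        k = cfg.tilt_window
        if k > 0:
            theta_ms = tilt_at_mid_stance(
                float(np.median(a_n[: k + 1])), float(np.median(a_t[: k + 1]))
            )
        else:
            theta_ms = tilt_at_mid_stance(float(a_n[0]), float(a_t[0]))
    else:
        # zero-tilt baseline: assume the shank vertical at mid-stance
        if a_n[0] <= 0:
            raise OrientationError(
                "normal acceleration not positive at mid-stance"
            )
        theta_ms = 0.0
    theta = integrate_orientation(omega, fs, theta_ms)
    a_v, a_ap = project_to_global(a_n, a_t, theta, cfg.g)
    S_v, S_ap, V_v, V_ap = integrate_displacements(a_v, a_ap, fs)
    return StrideKinematics(
        theta=theta, theta_ms=theta_ms, a_v=a_v, a_ap=a_ap,
        V_v=V_v, V_ap=V_ap, S_v=S_v, S_ap=S_ap,
    )


def estimate_slopes(rec: IMURecording, cfg: PipelineConfig | None = None) -> SlopeSeries:
    """Full pipeline: filter → detect mid-stance → segment → per-stride
    strapdown → slope series.

    The gyro trace is low-pass filtered for event detection only; the raw
    signals are used for integration.  Degenerate strides (|S_ap| below
    ``cfg.epsilon_displacement``) are flagged, not dropped.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate_for_fs(rec.fs)

    omega = rec.omega.copy()
    a_t = rec.a_t
    if cfg.omega_in_degrees:
        omega = np.deg2rad(omega)
    flip = cfg.flip_omega
    omega_f = zero_phase_lowpass(omega, rec.fs, cfg.cutoff_hz)
    if cfg.auto_flip and not flip and -np.min(omega_f) > np.max(omega_f):
        logger.warning(
            "dominant angular-speed lobe is negative; assuming mirrored "
            "mounting and flipping omega and a_t signs"
        )
        flip = True
    if flip:
        omega, omega_f, a_t = -omega, -omega_f, -a_t

    events = detect_mid_stance(omega_f, rec.fs, cfg)
    work = rec
    if flip or cfg.omega_in_degrees:
        work = IMURecording(
            time=rec.time, a_n=rec.a_n, a_t=a_t, omega=omega, fs=rec.fs,
            meta=rec.meta,
        )
    windows = segment_strides(work, events)

    slopes, mids, flags = [], [], []
    theta_ms_list, S_v_list, S_ap_list = [], [], []
    for i, win in enumerate(windows):
        try:
            kin = _stride_kinematics(win, rec.fs, cfg)
        except OrientationError as exc:
            raise OrientationError(f"stride {i} (tilt stage): {exc}") from exc
        val, degen = stride_slope(kin.S_v, kin.S_ap, cfg.epsilon_displacement)
        slopes.append(val)
        flags.append(degen)
        mids.append(0.5 * (win["time"][0] + win["time"][-1]))
        theta_ms_list.append(kin.theta_ms)
        S_v_list.append(kin.S_v)
        S_ap_list.append(kin.S_ap)

    truth = None
    if "slope" in rec.meta:
        truth = np.full(len(slopes), float(rec.meta["slope"]))
    return SlopeSeries(
        slopes=np.array(slopes),
        stride_times=np.array(mids),
        truth=truth,
        label="raw",
        flags=np.array(flags, dtype=bool),
        meta={
            "event_indices": events.indices,
            "theta_ms": np.array(theta_ms_list),
            "S_v": np.array(S_v_list),
            "S_ap": np.array(S_ap_list),
            "flipped": flip,
            **{k: v for k, v in rec.meta.items()},
        },
    )
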