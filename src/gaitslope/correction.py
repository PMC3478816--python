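"""Subject-specific linear calibration and stride-wise smoothing.

Raw per-stride slope estimates relate to the actual surface slope
approximately linearly, S_e = p·S_a + f.  Fitting p and f from walks at
two or more known inclinations and inverting, S_a = (S_e − f)/p,
removes subject-specific gain and offset.  Independently, a short
moving-average over consecutive strides reduces the random scatter of
estimates by ≈ √kernel while tracking slope changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as _stats

from .errors import CalibrationError, ValidationError
from .strapdown import SlopeSeries

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "moving_average",
]

_P_SINGULAR = 1e-6


@dataclass
class CalibrationModel:
    """Linear raw-vs-actual slope relation, raw = p·actual + f."""

    p: float                 #: gain (dimensionless)
    f: float                 #: bias (per-unit slope)
    n_points: int            #: strides used in the fit
    slopes_used: tuple       #: distinct known inclinations in the fit
    residual_sd: float = 0.0  #: SD of fit residuals (per-unit slope)

    def __post_init__(self) -> None:
        if abs(self.p) <= _P_SINGULAR:
            raise CalibrationError(f"gain p={self.p} is not invertible")
        if self.n_points < 2:
            raise CalibrationError("calibration needs at least 2 strides")
        if len(set(self.slopes_used)) < 2:
            raise CalibrationError(
                "calibration needs strides from at least 2 distinct slopes"
            )


def fit_calibration(raw: SlopeSeries | list[SlopeSeries]) -> CalibrationModel:
    """Ordinary least squares of raw estimate on actual slope.

    Accepts one truth-carrying :class:`SlopeSeries` or several (one per
    known-inclination walk); all non-degenerate strides are pooled.
    Requires at least two distinct known slopes — a single inclination
    cannot identify both gain and bias (walking the same ramp up and
    down provides two).
    """
    series = raw if isinstance(raw, list) else [raw]
    est_parts, truth_parts = [], []
    for s in series:
        if s.truth is None:
            raise CalibrationError("calibration requires ground-truth slopes")
        v = s.valid()
        est_parts.append(v.slopes)
        truth_parts.append(v.truth)
    est = np.concatenate(est_parts)
    truth = np.concatenate(truth_parts)
    if est.size < 2:
        raise CalibrationError("calibration needs at least 2 strides")
    distinct = np.unique(truth)
    if distinct.size < 2:
        raise CalibrationError(
            "strides from only one known slope: gain and bias are not "
            "identifiable (walk the same ramp in both directions to get two)"
        )
    fit = _stats.linregress(truth, est)
    resid = est - (fit.slope * truth + fit.intercept)
    return CalibrationModel(
        p=float(fit.slope),
        f=float(fit.intercept),
        n_points=int(est.size),
        slopes_used=tuple(float(x) for x in distinct),
        residual_sd=float(np.std(resid, ddof=2)) if est.size > 2 else 0.0,
    )


def apply_calibration(raw: SlopeSeries, model: CalibrationModel) -> SlopeSeries:
    """Invert the linear relation element-wise: (Θ − f) / p."""
    if abs(model.p) <= _P_SINGULAR:
        raise CalibrationError(f"gain p={model.p} is not invertible")
    return replace(
        raw,
        slopes=(raw.slopes - model.f) / model.p,
        label="calibrated",
        meta={**raw.meta, "calibration": (model.p, model.f)},
    )


def moving_average(
    slopes: SlopeSeries | np.ndarray, kernel: int = 5, causal: bool = False
) -> SlopeSeries | np.ndarray:
    """Moving average over consecutive strides.

    Centered by default (offline use; sharpest step response for a given
    noise reduction); ``causal=True`` gives the trailing window an
    online system would use.  Edges shrink the window to the available
    neighbors, so the output has the input's length.  Apply within one
    recording only — averaging across walks at different slopes mixes
    regimes.
    """
    if isinstance(slopes, SlopeSeries):
        out = moving_average(slopes.slopes, kernel=kernel, causal=causal)
        return replace(slopes, slopes=out, label="smoothed")
    x = np.asarray(slopes, dtype=float)
    if not (kernel >= 1 and kernel % 2 == 1):
        raise ValidationError("kernel must be an odd integer >= 1")
    if kernel > x.size:
        raise ValidationError(
            f"kernel {kernel} longer than series of length {x.size}"
        )
    out = np.empty_like(x)
    half = kernel // 2
    for i in range(x.size):
        if causal:
            lo, hi = max(0, i - kernel + 1), i
        else:
            h = min(half, i, x.size - 1 - i)
            lo, hi = i - h, i + h
        out[i] = x[lo : hi + 1].mean()
    return out
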