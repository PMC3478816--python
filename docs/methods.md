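# Methods

## Model and assumptions

The estimator treats each stride as an independent strapdown problem in
the sagittal plane.  Its assumptions, all anchored at mid-stance:

- **Pendular stance.**  The stance leg pivots about the foot; at
  mid-stance the shank's angular speed passes through a shallow maximum
  of its negative lobe, and both the linear velocity and the linear
  acceleration of a point on the shank are negligible.  The tangential
  acceleration of a pendulum point is r·dω/dt and the normal
  (centripetal) one is r·ω², so with ω ≈ 0 and dω/dt ≈ 0 at mid-stance
  the accelerometer senses gravity alone there.
- **Inclinometer initialization.**  Under the gravity-only assumption,
  θ_MS = arctan(a_t/a_n) is the shank tilt from vertical.  This is the
  step that distinguishes the method from walking-speed strapdown
  pipelines that assume θ_MS = 0; on sloped ground the shank is *not*
  vertical at mid-stance and that assumption injects a systematic slope
  bias (see "sign of the baseline bias" below).
- **Per-stride integration.**  Orientation and displacement are
  integrated only across one stride and re-initialized at the next
  mid-stance, so gyro drift cannot accumulate beyond a stride.
- **Planarity.**  Only sagittal kinematics are modelled; out-of-plane
  motion is treated as noise.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `g` | 9.8 | m/s² | gravity used in the frame projection |
| `cutoff_hz` | 4 | Hz | zero-phase low-pass for event detection; gait's dominant harmonics (≈0.9, 1.8 Hz) pass intact, tremor/impact content is removed |
| `ma_kernel` | 5 | strides | moving-average length; SD shrinks ≈ √5 while still tracking slope changes within a few strides |
| `min_stride_s` | 0.4 | s | events closer than this are merged (keeps the larger filtered ω) |
| `swing_peak_quantile` | 0.7 | — | swing peaks must exceed this fraction of the global filtered-ω maximum |
| `epsilon_displacement` | 0.05 | m | strides with \|S_ap\| below this are flagged degenerate instead of dividing by ≈0 |
| `tilt_window` | 0 | samples | optional ±k-sample median for the mid-stance accelerometer read, for jittery event timing |

The filter is a 2nd-order Butterworth applied forward–backward with
Gustafsson initial conditions, chosen so the result is exactly
equivariant under time reversal: detected event times are not skewed by
direction-dependent edge transients.  All integrals are cumulative
trapezoids; at 100 Hz the trapezoid truncation error contributes less
than 10⁻⁴ of slope per stride, far below the sensor-noise floor.

Angular speed is assumed rad/s (`omega_in_degrees` converts).  If the
dominant filtered-ω lobe is negative the pipeline assumes a mirrored
mounting and flips both ω and a_t — a mediolateral mirror flips those
two axes together — logging a warning.

## Event detection

"Lower-lobe maximum" is operationalized as the most *prominent*
strictly-interior local maximum of filtered ω among samples with ω < 0
between consecutive swing peaks, ties going to the earliest sample.
Prominence, not raw value, is used because with noise the samples just
inside a zero crossing are local maxima arbitrarily close to zero and
would otherwise always beat the true mid-stance hump; the hump, rising
out of the deep post-heel-strike and pre-toe-off troughs, dominates on
prominence.

## The synthetic gait generator

One stride occupies one period T, phase u = t/T with mid-stance at
integer u.  The generator emits

- ω(t) = (A/T)·[cos 4πu − (1+η) cos 2πu], with A = 1.2 rad and
  η = 0.02: a single positive swing lobe per cycle (peak ≈ 2.2 rad/s at
  the defaults) and one negative stance lobe whose interior maximum sits
  exactly at mid-stance with value −ηA/T ≈ −0.02 rad/s;
- θ(t) = θ_MS + A·[sin 4πu/4π − (1+η) sin 2πu/2π], so the tilt at every
  mid-stance is exactly θ_MS (default: tilt_gain · slope, tilt_gain 1 —
  a stand-in for the unknown real tilt-vs-grade relation, exposed as a
  parameter);
- a sensor point advancing along the inclined line, x = L·[u − sin 2πu/2π],
  y = slope·x, whose velocity *and* acceleration vanish exactly at
  mid-stance and which advances exactly one stride length L = speed·T
  per stride, so the true per-stride S_v/S_ap equals the scenario slope
  identically;
- sensor channels as the true specific force rotated into the shank
  frame, plus i.i.d. Gaussian noise (defaults: accelerometer 0.1 m/s²,
  gyro 0.01 rad/s — generator choices, not device data; they produce a
  per-stride slope scatter of ≈ 0.015–0.02 at the default gait) and an
  optional constant gyro bias.

Recordings are padded by 1.5 strides per side so all reported
mid-stance instants are detectable; a scenario whose construction
cannot keep |ω| at mid-stance under 0.05 rad/s (e.g. a very short
stride time) raises a construction error naming the constraint.

Assumption violations are injected as zero-mean periodic perturbations
peaking at mid-stance: `residual_omega_ms` deepens the gyro lobe by m
and adds the pendulum centripetal term r·(m cos 2πu)² to the normal
channel (so a_n at mid-stance departs from g by exactly ω²r);
`residual_accel_ms` leaves m of forward acceleration at mid-stance,
corrupting the tilt reading by ≈ m/g rad; `gyro_bias` offsets the gyro.

**What the simulator does not emulate:** double support, ground
reaction transients, stride-to-stride timing variability, soft-tissue
artefact, 3-D motion, or any empirical tilt-vs-grade law.  Passing
tests therefore validate the *estimator's* correctness and its
sensitivity structure, not its accuracy on real recordings.

## Sign of the baseline bias

With this package's conventions (θ positive = shank top leaning
forward; tangential axis forward at vertical, so forward walking gives
S_ap > 0), suppressing a mid-stance tilt δ rotates the reconstructed
global frame by δ: +g sin δ leaks into the antero-posterior channel
(inflating S_ap by g sin δ·T²/2 per stride) and −δ·a_ap into the
vertical one (deflating S_v by ≈ δ·L).  The resulting slope bias is
therefore *opposite* in sign to the suppressed tilt, deterministically;
the tests assert exactly this relation.

## Numerical choices and degenerate inputs

- Cumulative trapezoid everywhere; θ[0] equals θ_MS exactly and initial
  velocities are exactly zero.
- Calibration regresses raw on actual (as the relation is defined) and
  inverts; a gain |p| ≤ 10⁻⁶ or a single known slope is an error.  The
  residual SD of the fit is reported as a diagnostic.
- The moving average is centered with shrinking symmetric edge windows
  (output length = input length); a `causal` flag gives the trailing
  variant for online use.  Note the shrinking-edge scheme does not
  preserve the series mean exactly — edge samples carry extra weight —
  but interior samples match the uniform kernel exactly.
- Strides with |S_ap| ≤ 0.05 m are flagged degenerate and excluded from
  metrics by default rather than dropped silently; backward strides
  (S_ap < 0) keep their signed ratio and surface through the flag.
- Metrics use sample SDs (ddof = 1); global accuracy pools all stride
  errors rather than averaging per-subject means.

## Problem sizes

Tests run simulations of 8–90 strides at 100–400 Hz; the synthetic
study replication uses 6 pseudo-subjects × 7 grades × 90 strides.  The
acceptance script uses 30-stride noiseless walks at 100 Hz.

## Known limitations

- The tilt-vs-grade relation of real walking is unknown to the
  generator; `tilt_gain` is a knob, not physiology.
- Real per-stride scatter (≈ 0.03–0.06) exceeds the synthetic default;
  conclusions about absolute RMSE on real data cannot be drawn from the
  simulator.
- Detection presumes one dominant swing lobe per cycle; pathological or
  very slow gait may violate it (the detector then errs loudly).
- Gyro biases larger than the stance-lobe depth lift the lower lobe
  above zero, where mid-stance detection is by definition impossible.
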