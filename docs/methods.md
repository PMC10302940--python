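# Methods

## Model and assumptions

The arm is a planar two-link chain. The shoulder is a fixed rotation-only
joint at the origin of the X–Y plane; the upper arm (length `l1`, cm) rotates
by the shoulder angle θ₁, the forearm (length `l2`, cm) by the relative elbow
flexion θ₂. Forward kinematics place the elbow at `l1_eff·(cos θ₁, sin θ₁)`
and the wrist at the elbow plus `l2·(cos(θ₁+θ₂), sin(θ₁+θ₂))`. Out-of-plane
motion, shoulder translation and full 3-D articulation are outside the model:
everything is the X–Y projection. The upper-arm length carries a scalar
"muscle contraction" fluctuation `l1_eff(t)`; no other soft-tissue artifact is
modelled.

The wrist IMU frame is aligned with the distal forearm segment, so its yaw
equals θ₁+θ₂ — this is what makes the yaw usable for disambiguating the two
geometric elbow candidates. Accelerometers follow the reaction (specific
force) convention: a stationary, level sensor reads `(0, 0, +g)`.

## Synthetic study conditions

No public recordings exist for this task, so the generator defines the study
conditions; all values are config-exposed and seeded.

| parameter | default | rationale |
|---|---|---|
| sampling rate | 100 Hz (Δt = 0.01 s) | typical wearable-IMU rate |
| l1, l2 | 30 cm, 25 cm | adult upper-arm / forearm scale |
| motion | stance/swing sweeps, period 2.5 s, 40% stance, quintic ease | reach-and-hold movement with C² angle profiles (continuous synthetic accelerations) |
| contraction amplitude | 0.5 cm | matches the ~0.5 cm peak effect reported for hand-squeeze on the upper arm |
| accel noise / bias | 0.05 m/s² / 0.02 m/s² | low-cost MEMS class |
| gyro noise / bias | 0.005 rad/s / 0.002 rad/s | low-cost MEMS class |
| pixel calibration | 0.042 cm/px, 1 px jitter | the reference camera calibration |

The contraction fluctuation is a 1.2 Hz sinusoid whose envelope is modulated
±8% by low-passed noise, so individual peak deviations scatter around the
requested amplitude — matching how the effect is quantified downstream (mean
peak deviation). The generator's ground-truth stationarity mask thresholds
the wrist speed and the sensor yaw rate from central differences.

What the generator does **not** emulate: out-of-plane wobble, time-varying
sensor bias, magnetometer disturbance, camera occlusion and rolling shutter,
marker deformation. Passing tests therefore demonstrate the correctness of
the algorithms under the stated planar model, not field performance on real
limbs.

## Zero-velocity detector

The windowed GLRT combines accelerometer deviation from the window-mean
gravity direction with gyroscope energy, normalised by the sensor noise
variances σₐ², σ_ω². Window stride is 1 sample and accepted windows are
OR-combined into the per-sample mask (a sample is stationary if any accepted
window covers it); the mapping from window decisions to samples is not
otherwise constrained by the method, and OR-combination is the permissive
choice consistent with using the flags as ZUPT triggers.

σₐ², σ_ω² are *sensor noise descriptions*, not free tuning: the defaults equal
the squared generator noise levels, and a zero-noise configuration should set
them near zero (the test suite uses 10⁻⁸). γ defaults to 300, chosen by
sweeping stance-classification F1 on the default synthetic gait; the
operating plateau is wide (stationary windows score ≈ 6–8 under the default
noise, swing windows score > 10⁴). A window whose mean specific force has
norm < 10⁻⁹ raises a degenerate-window error rather than dividing by zero.

## Error-state EKF with ZUPT

The nominal state is propagated by the strapdown transcription above; the
quaternion update uses the exact rotation-vector increment `q ⊗ δq(ωΔt)`,
which is first-order equivalent to the linearised quaternion-rate form and
preserves the unit norm by construction (renormalised each step regardless).

The 9-dimensional error state (δp, δv, δθ) uses a **world-frame** attitude
error, `R_true = Exp([δθ]×)·R_nom`. First-order transition:

    δp' = δp + δv·Δt
    δv' = δv − [R·a_body]× δθ·Δt
    δθ' = δθ

Discrete process noise is `Q_v = (σ_a Δt)² I`, `Q_θ = (σ_g Δt)² I`; the
covariance is symmetrised after every propagation and update. The ZUPT
measurement is `z = −v` with `H = [0 I 0]` and noise (0.01 m/s)²; the update
uses the Joseph form, the error estimate is injected (quaternion corrected by
a world-frame small rotation) and reset to zero. Sensor biases are *not*
estimated — the filter's drift reduction comes entirely from the ZUPTs, which
is the effect the drift-halving test quantifies.

Between consecutive IMU samples the filter loop uses a two-sample refinement
(`propagate_pair`): trapezoidal integration of the angular rate and of the
world-frame acceleration for the velocity row, zero-order hold for the
position row. This is the standard strapdown two-sample update; it is the
exact inverse of central-difference-synthesised accelerations, which the
noiseless round-trip test exploits (elbow RMSE < 0.1 cm end to end). The
plain single-sample step is kept as `propagate` and is the literal
transcription of the model equations.

Initial attitude comes from levelling on the mean accelerometer of an initial
stationary span (yaw unobservable from gravity, set from external knowledge
or zero); the demo pipeline initialises position and yaw from the known first
wrist sample, as the method assumes an initial position configuration.

## Elbow geometry

`circle_circle_intersect` reduces the two-circle system via the radical line
`2ax + 2by = a² + b² + l1² − l2²` and returns 0–2 candidates; tangency within
10⁻⁹·max(1, l1²) collapses to one point, concentric circles raise a
degenerate-geometry error. Branch selection: (1) the candidate whose
elbow→wrist heading best matches the IMU yaw α; (2) minimal displacement from
the previous elbow; (3) the upper candidate (larger y), flagged, as the
anatomical default.

Wrist observations outside the reachable annulus `[|l1−l2|, l1+l2]` are
clamped radially when within 1% of (l1+l2) — sized to absorb the ~0.5 cm
contraction fluctuation — and rejected beyond that. Downstream of the EKF the
pipeline clamps unconditionally (`tolerance=inf`): a drifting position
estimate is still the best available wrist observation, and aborting
mid-trace would discard the remaining data.

## Pyramid match and NCC

The histogram pyramid follows the standard construction: side-`2^i` bins at
level i (L = log₂D + 1 levels, domain side padded up to a power of two,
points never rescaled), sparse storage of occupied bins only. The match score
counts newly co-binned points level by level via min-intersection, weighted
`1/2^i` — so identical sets score |X| and points matched only at the coarsest
level contribute `1/2^{L−1}`. The exact score normalisation used by the
reference vision toolchain is not disclosed; this weighting is the standard
one and is validated against a Hungarian optimal-assignment oracle in the
tests. NCC matching delegates to `skimage.feature.match_template`; a
constant template raises, correlations are clipped to [−1, 1], and per-frame
detections below a correlation floor are flagged as gaps, never interpolated.
The "pyramidal matching vs image understanding" dichotomy is collapsed onto
one NCC engine.

## Paired statistics

All variances are sample variances (n−1). That convention is what makes the
summary-statistics route

    t = (m₁ − m₂) / sqrt((v₁ + v₂ − 2·r·s₁·s₂) / n)

algebraically identical to the textbook per-difference t, which the
consistency tests assert to 10⁻¹⁰. p-values are two-tailed from `scipy.stats.t`
with df = n−1. Zero difference variance with a nonzero mean difference is
reported as an infinite-t flag rather than an exception. The l1 metric
("mean peak deviation") takes local maxima of |l1_eff − l1| with a minimum
prominence of 0.05 cm — a tenth of the default effect size — since the
quantity is defined without a peak criterion.

## Numerical choices and degenerate inputs

- Quaternion norm enforced to 10⁻⁶ on input and renormalised after every
  update; rotation-vector quaternions use a second-order small-angle
  expansion below 10⁻¹² rad.
- Covariances validated symmetric-PSD (eigenvalue floor −10⁻⁹) before use;
  Joseph-form ZUPT update; innovation condition number capped at 10¹⁴.
- Traces shorter than 3 samples cannot be differentiated twice and are
  rejected; IMU synthesis replicates edge accelerations.
- Empty traces filter to empty results; empty point sets build pyramids with
  the correct level count.

## Known limitations

- Planar model only; the real shoulder also translates, which the method does
  not capture — agreement on the Y axis degrades accordingly in any realistic
  setting.
- No bias estimation in the filter: long swing phases accumulate bias-driven
  drift that only the next stance removes.
- Branch selection can still flip under large simultaneous yaw error and
  near-tangency; the branch label and clamp flag are exported so downstream
  code can audit such samples.
- The acceptance comparison reproduces the published summary-statistics t
  values exactly; the published raw-recording quantities (per-axis SDs,
  Pearson values, 0.516 cm peak deviation) depend on unreleased recordings
  and are represented here only by the planted-parameter recovery tests.
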