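# Methods

## Sensing model

A shoe insole on the right foot carries a triaxial accelerometer and
eight plantar pressure sensors, each reporting a 2-bit pressing level,
all sampled at a nominal 50 Hz. The eight levels are fused into one
16-bit pressure word with Sensor 1 (first-metatarsal area) in bits 15–14
down to Sensor 8 (heel edge) in bits 1–0. The word is bijective with the
level vector (`codec` module, exhaustively tested over all 65536 words);
only the binary swing/stance information is consumed today, but the full
levels are preserved for future phase-level analysis.

Recordings are CSVs (`t,ax,ay,az,pressure`) with a JSON sidecar for the
sampling rate, subject and reference distance. Acceleration is stored in
m/s² so double integration yields metres. Timestamps are explicit and
must be uniformly spaced at 1/fs (relative tolerance 1e-6); gaps are an
input error, never silently repaired.

## Gravity separation

Per axis, gravity is tracked with the exponential low-pass

    g(t) = α·g(t−1) + (1−α)·a_raw(t),   α = 0.8,

and linear acceleration is `a = a_raw − g`. At 50 Hz this one-pole filter
has an equivalent cutoff near 1.8 Hz, so it also attenuates part of the
genuine swing dynamics (fundamental ≈ 2.5 Hz for a 0.4 s swing); the
resulting distortion is deterministic and common to all strides of a
given gait geometry, and is absorbed by the calibration coefficient K.
The recurrence is implemented as a `scipy.signal.lfilter` one-pole with
the initial state folded into the filter's initial condition; a
brute-force loop oracle checks exact agreement.

Initialisation is open in principle; the default seeds g(0) with the
first raw sample, which is exact when the recording starts at rest (the
standard protocol: the subject stands still before walking). A zero-init
option exists for analysis and testing.

## Band-pass stage

A Butterworth band-pass (defaults 5–10 Hz, order 2) can be applied to the
linear acceleration. It runs forward-backward (zero phase) so the
filtered signal stays time-aligned with the pressure-derived swing mask —
phase lag here would desynchronise the mask and the acceleration it
gates. Pressure words are discrete states and are never filtered.

The 5–10 Hz band lies **above** the dominant stride-displacement band
(~1–3 Hz), so applying it suppresses most of the metre-scale displacement
signal. The stage is therefore switchable (`enabled`) with overridable
corners; distance estimation and calibration on clean synthetic signals
run with it disabled, while the segmentation and counting results are
independent of it (they consume pressure only). Whether the band-pass
belongs before or after gravity separation, and to which signals, is
genuinely ambiguous; the pipeline applies it after gravity separation and
leaves it off by explicit choice in the distance tests rather than
silently altering the corners.

## Swing segmentation and stride counting

The per-sample swing indicator is

    F(k) = 1  ⇔  p(k) ≤ threshold,   threshold = 1.

Swing requires *all* sensors off, with one documented exception: Sensor 8
sometimes reports "slightly pressed" (level 1, word exactly 1) during
late swing, just before heel strike. The inclusive cutoff at 1 absorbs
exactly that artifact. (Stated the other way round — swing when the word
is *at or above* the threshold — the rule would classify full stance as
swing, contradicting the all-sensors-off requirement; the inequality
orientation implemented here is the one consistent with that
requirement, and a segmentation test documents that a threshold of 0
breaks counting when glitches are present.)

Debouncing: swing runs shorter than `min_swing_samples` are flipped to
stance, then interior stance runs shorter than `min_stance_samples` are
flipped to swing. Defaults of 5 samples (0.1 s at 50 Hz) sit far below
physiological swing (~0.4 s) and stance (~0.6 s) durations, so real
phases are never suppressed; the operation is a fixed point under
re-application. Swing runs touching either recording boundary are
incomplete (lift-off or landing not captured) and are dropped with a
warning rather than integrated; the standard start/stop-standing protocol
makes complete runs the expected case.

One complete swing phase = one stride; the stride count is the number of
complete swing runs.

## Distance estimation

Over each swing the acceleration magnitude and the vertical component are
double-integrated with the rectangular (left-endpoint) rule, velocity
reset to zero at swing start (the zero-velocity-at-stance assumption):

    vMAG[k] = Σ_{j≤k} a[j]·Δt     dMAG = Σ_k vMAG[k]·Δt
    vz[k]   = Σ_{j≤k} az[j]·Δt    dz   = Σ_k vz[k]·Δt

The rectangular rule is kept deliberately rather than upgraded to
trapezoidal: K absorbs the quadrature constant, and fidelity to the
defining sums keeps the implementation exactly checkable against loop
oracles (agreement to 1e-12 relative is asserted).

The cumulative estimate is the online update

    d[n] = d[n−1] + K·dMAG[n]/|dz[n]| + L0,   d[0] = 0,

with L0 = 0.26 m (average foot length) added once per stride. The
absolute value on dz is a design choice: over a lift-and-land swing the
signed vertical displacement can be near zero or negative, and only its
magnitude is meaningful as a normaliser. Strides with |dz| below
`dz_epsilon` (default 1 mm) are flagged and fall back to the median ratio
of the unflagged strides in the recording; a recording where every stride
is flagged is a hard error, not a guess. The recursive update and the
batch form `K·Σ ratio + N·L0` are exactly equivalent (tested), and the
estimator is invariant to a common rescaling of all accelerations, since
the scale cancels in dMAG/dz.

The first swing after standing still is physiologically a step rather
than a full stride; it is treated like any other stride, since the
swing-phase displacement, not the stance history, carries the distance
information.

## Calibration and evaluation

Because the estimate is linear in K, the coefficient that reproduces a
labelled walk exactly is the algebraic inversion

    K_i = (d_ref − N_i·L0) / Σ_n ratio[n]_i ,

and a training set's K is the arithmetic mean of its per-walk
coefficients — equivalent, for each walk, to tuning K until the estimate
matches the reference, but exact and deterministic. Evaluation follows
leave-one-out cross-validation: hold out each walk, fit on the rest,
estimate the held-out distance. Each walk is measured once and the folds
reuse the cached per-walk sums, so LOOCV is O(walks) pipeline runs.

The error statistic is the mean **absolute** relative error
`e = (1/N) Σ |d_m − d_ref| / d_ref`: per-subject error tables cannot be
reproduced by signed means (a group can have its mean estimate almost on
the reference yet a clearly nonzero error), so absolute deviations are
the only consistent reading. Summary statistics (mean, median, min, max,
sample SD) accompany the error.

## Synthetic gait simulator

The simulator generates recordings with exact ground truth (stride count,
swing transition times, total distance, trajectory-implied per-stride
ratios). Per stride the foot follows a closed-form lift-advance-land
curve: forward advance is a minimum-jerk ramp of the stride length (zero
velocity and acceleration at both ends), vertical motion a half-sine of
the lift height. Stance is motionless. Accelerations are the exact
backward second differences of the sampled trajectory, so the pipeline's
rectangular quadrature recovers the sampled displacement to machine
precision — ground truth and pipeline are linked mathematically, which is
what makes parameter-recovery tests meaningful. The velocity jumps at
toe-off and landing appear as single-sample acceleration impulses, the
discrete analogue of push-off and impact transients.

Gravity (default (0, 0, 9.81) m/s²) is injected into the raw signals so
the separation recurrence is exercised end to end, then optional white
Gaussian noise is added. Stance pressure follows a four-phase
heel-strike → loading → flat → heel-off activation template over the
eight sensors (word always above the segmentation threshold); swing
pressure is zero except for optional injected Sensor-8 word-1 glitches in
the last quarter of the swing.

Defaults model the study conditions: 50 Hz sampling; 0.4 s swing and
0.6 s stance (a 1 s gait cycle); 1.25 m strides, which with the stance
lead-in puts average speed at ≈1.2 m/s, inside the observed 1–1.6 m/s
band (asserted by a test); 5 cm foot lift; 5% per-stride length jitter;
0.3 m/s² per-axis noise, typical of a consumer MEMS accelerometer
strapped to a shoe. `simulate_database` emulates walking a fixed course:
per-stride lengths are jittered and renormalised so every walk covers
exactly the reference distance, with per-walk seeds derived
deterministically from a master seed.

What the simulator does **not** model — and hence what passing tests do
not show about real data: soft-tissue and shoe-sole transfer functions,
accelerometer bias/scale error and axis misalignment, foot-frame rotation
during swing (the simulated sensor frame stays aligned with the world
frame), left/right asymmetry, dragging feet or other pathological gaits,
and turning. Real calibration coefficients will differ from synthetic
ones; what the tests establish is the internal consistency of the
pipeline and the exactness of its algebra, plus graceful degradation with
noise (the held-out error grows smoothly with the injected noise
amplitude).

## Numerical and design notes

- Problem sizes: the acceptance-style checks use 50 simulated recordings
  of 5–100 strides for counting and an 84-walk 16 m database (12 strides
  per walk) for calibration — a full-size analogue of the short-distance
  study arm; the whole suite runs in a few seconds.
- All randomness flows through `numpy.random.default_rng` seeds; fixed
  seeds give bit-identical recordings.
- CSV floats are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-exact.
- The per-stride integrals expose both the signed dz and the |dz|-based
  ratio, so downstream analysis can revisit the sign convention.
- Error handling is fail-fast: non-uniform sampling, out-of-range
  pressure words, zero detected strides and degenerate vertical
  displacement are named errors (distinct CLI exit codes), never silent
  repairs.

## Known limitations

- The dMAG/|dz| ratio of a clean, drift-free swing depends on processing
  artifacts (gravity-filter response, velocity-reset truncation) as much
  as on geometry; K is therefore a property of the *whole* pipeline
  configuration, and a model fitted under one configuration (e.g.
  band-pass off) is not transferable to another.
- Calibration is per walk set: walks over different courses (16 m vs
  89 m) should be calibrated separately unless shown to share K.
- Stairs, running, turning and pathological gaits are out of scope; the
  segmentation assumes the foot actually clears the ground each stride.
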