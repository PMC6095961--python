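# Methods

## Signal model and feature extraction

The package operates on single-channel surface MMG sampled at 1 kHz,
optionally paired with dynamometer knee torque at 500 Hz. The raw MMG is
band-pass filtered to 20–200 Hz — the band where muscle vibration carries
its energy — with a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`). The realization is a design choice: zero-phase filtering
avoids phase distortion at the 1-second epoch boundaries the features are
computed on; order and corners are configurable.

Both channels are cut into non-overlapping 1 s epochs; a trailing partial
epoch is discarded. Per epoch the amplitude feature is the RMS over all N
samples, `sqrt((1/N) Σ_{k=1..N} x_k²)`. The frequency surrogate is the
zero-crossing count `Σ sgn(−x_k·x_{k+1})` with `sgn(x)=1` for x>0 and 0
otherwise, i.e. only strictly opposite-signed neighbours count and a zero
sample contributes no crossing; this convention matters because ZC
definitions vary across the literature, and is asserted by tests. Torque is
reduced to the epoch mean (500 samples per epoch at 500 Hz).

Feature and torque series are normalized by their **per-trial maximum**
rather than min-max: downstream statistics are phrased as "drop to X% of
maximum", which requires fractions of the peak, and both RMS and torque are
nonnegative so the range stays [0, 1]. Per-trial (not per-session-pool)
normalization is an assumption; each trial's divisor is retained so
physical units can be recovered.

## Torque regressor

A feed-forward perceptron with one hidden layer of 10 logistic-sigmoid
units and a linear output maps normalized features (RMS, or RMS and ZC) to
normalized torque: `z = W2·σ(W1 u + b1) + b2`, output unclipped. Weights
are initialized uniformly in [−0.5, 0.5] from a seeded generator.

Training is a from-scratch Levenberg–Marquardt least-squares loop on the
residuals e = R − z:

* Δw = [JᵀJ + μI]⁻¹ Jᵀe, with J the analytic Jacobian ∂z/∂w over all 31
  (RMS) or 41 (RMS+ZC) weights and biases; finite differences are kept in
  the tests as an independent oracle.
* μ starts at 1e-3; an accepted step (training SSE strictly decreases)
  divides μ by 10, a rejected one multiplies by 10 and retries. μ > 1e10
  aborts. Training SSE is therefore non-increasing over accepted steps by
  construction, and the per-epoch record asserts it.
* Samples are split 70/15/15 into train/validation/test partitions by a
  seeded per-sample shuffle. Early stopping triggers after 6 consecutive
  validation-SSE increases; the weights returned are those of the best
  validation epoch. Other stops: 1000-epoch budget and an infinity-norm
  gradient tolerance of 1e-7.

These schedule constants are standard damped-Gauss–Newton practice and are
all exposed in `TrainConfig`. A per-trial (rather than per-sample) split is
available by building the dataset per trial and splitting trial lists.

## Fatigue statistics

**Drop times.** The time to an X% drop is the earliest epoch at which the
max-normalized series is ≤ X. Torque-like series are first smoothed with a
5 s moving average (configurable; 0 disables) because noisy predictions
make raw first crossings unstable. Timing accuracy is
`(1 − |t_pred − t_actual|/t_actual) × 100`, deliberately unclamped: a
prediction that misses by more than the actual time goes negative, and
clamping would hide exactly the failures the statistic exists to expose.

**Critical point.** The fatigue gradient-change point is found by fitting
a continuous two-segment piecewise-linear ("hinge") model
`y = β0 + β1 t + β2 (t − t_b)+` at every interior epoch, excluding 3
boundary epochs on each side to avoid near-degenerate one-sided segments,
and taking the breakpoint with minimal total SSE (ties → earliest). The
search is exhaustive at this scale (a few hundred candidates), so SSE
optimality is asserted directly in tests. A perfectly linear series sets a
`degenerate` flag (no hinge beats the single line by more than a relative
1e-8).

**Hypothesis battery.** Across standing sessions, per model variant:
initial vs final predicted torque (means of the first/last 5 epochs);
pre- vs post-50%-drop least-squares gradients of RMS, ZC and predicted
torque (slopes in normalized units per second over each full side); and
cross-variant comparisons of critical-point time and torque. All tests are
paired two-tailed t-tests — observations pair naturally within sessions —
with Welch's unpaired test available for unequal designs. Zero-variance
pairs make the paired statistic undefined; that surfaces as "n/a" rather
than a fabricated p-value.

## Synthetic session generator

The generator is phenomenological: it reproduces the feature-level
structure of FES-evoked fatiguing contractions, not the underlying
electrophysiology.

* **Torque**: T(t) = floor + (1 − floor)/(1 + exp(r(t − t_mid))), with
  t_mid placed so T equals 0.95 at the decline onset `t_onset_s`. The
  closed form gives analytic ground-truth crossing times (`t_50_s`).
  Defaults: 300 s sessions, onset 60 s, rate 0.045 /s, floor 0.3 of
  maximum — a session that declines "well below 50%", ending near its
  floor. Dynamometer noise (0.5 N·m on raw samples) averages to ~0.03 N·m
  per epoch mean.
* **MMG**: unit-variance band-limited Gaussian noise multiplied by the
  envelope `0.02 + 0.2·T(t)` volts plus white noise (sd 0.01 V). The
  carrier band crossfades from 40–80 Hz to 80–160 Hz over 10 s starting at
  the 50% torque crossing, modelling the shift toward faster contractile
  dynamics as fast-twitch fibres dominate; this drives the late-session ZC
  rise without simulating motor units.
* **Standing mode**: no torque channel (the premise is that stance torque
  is unmeasurable); instead a knee-flexion angle
  θ = 30·(0.5 − T)/(0.5 − (floor + 0.02)), clipped to [0, 30]°, stays at
  0° while T ≥ 0.5 and reaches the 30° buckle endpoint when T falls to
  floor + 0.02; the session is truncated there (whole seconds, so epochs
  stay aligned). The 0.02 margin makes the buckle time finite on the
  asymptotic logistic. An optional buckle artifact ramps the MMG envelope
  up (×2 by session end, starting at 85% of the duration), emulating the
  amplitude surge seen when the knee gives way. It is off by default: it
  is a mechanical disturbance of the posture, not part of the fatigue
  signal, and with it enabled the single-hinge critical-point fit locks
  onto the end surge rather than the fatigue bend.
* **Cohorts** draw per-session parameters uniformly: onset 40–80 s, rate
  0.03–0.06 /s, floor 0.25–0.35, peak torque 25–45 N·m, envelope gain
  0.18–0.22 V, noise 0.008–0.012 V; every session gets its own seed derived
  from the master seed, so a cohort is reproducible from one integer.

The generator stores two change-point labels: `t_onset_s` (the T = 0.95
threshold) and `t_gradient_change_s`, the hinge breakpoint of the
*noiseless* per-epoch torque profile. The latter is the correct target for
a gradient-change detector — on a logistic the best two-segment
approximation bends 2–4 normalized-time points after the 5% decline
threshold purely from curve geometry.

## What passing tests do and do not show

Synthetic sessions share the real signals' qualitative structure (amplitude
tracks torque; spectral content rises past the 50% drop; plateau-then-
decline torque) but are idealized: the amplitude–torque relation is exactly
affine, noise is Gaussian and stationary, there are no stimulation
artifacts, no movement disturbances (except the optional buckle ramp), no
inter-subject variability in the feature–torque mapping beyond the sampled
gain, and no day-to-day electrode-placement effects. Recovery results on
this cohort (held-out r ≈ 0.99, timing accuracy ≈ 97%) are therefore upper
bounds on, not estimates of, performance on patient recordings — published
values on real data of this kind are nearer r ≈ 0.85 and 80–86% accuracy.

One quantified pipeline bias is worth knowing: a 1 s epoch of 40–80 Hz
band noise estimates RMS with ~8% relative error, and this input noise
attenuates the learned feature→torque mapping near the plateau (predictions
compress above ~0.8 of maximum). The detected critical point consequently
lands, on average, ~5 normalized-time points late of the true profile
gradient change, occasionally up to ~10 on individual sessions. The
acceptance test for critical-point recovery therefore checks the
cohort-mean absolute deviation (≤ 10 points over 20 sessions), not each
session individually.

## Problem sizes and numerical choices

The shipped analyses use 30 extension trials (18 train / 12 held out) of
300 s and 20 standing sessions — matching the scale of the study design the
package mirrors — which keeps the full pipeline under a minute on one CPU.
Degenerate inputs are handled explicitly rather than silently: all-zero
series refuse max-normalization; identical t-test pairs raise; sessions
shorter than one epoch yield empty feature series; drop thresholds never
reached return a sentinel that propagates as "undefined accuracy". Channel
files carry explicit time stamps, and the declared sampling rate is
validated against them (1 ns tolerance plus a few ulps for long
recordings), never inferred.
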