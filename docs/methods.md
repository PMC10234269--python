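# Methods

## The analysis

During steady treadmill walking, where a foot lands in the
anterior-posterior (AP) direction is tightly coupled to the body's
center-of-mass (CoM) state. The package implements the two-stage analysis
of whether deviations from that coupling are corrected by ankle push-off in
the following double stance.

**Stage 1 — foot-placement model.** Steps are defined from heel strike to
contralateral heel strike, with a phase variable j running 0–100% over the
step. At every phase sample the de-meaned AP foot placement of step i
(distance between trailing and leading heel at the closing heel strike) is
regressed, without intercept, on the de-meaned CoM states at that phase:

    FP_i = beta_pos(j) * CoM_pos,i(j) + beta_vel(j) * CoM_vel,i(j) + eps_i(j)

CoM position is expressed relative to the stance (trailing) foot; the
regression is fitted independently per phase, per participant, per placing
foot and per condition. The residual at j = 100% is the foot-placement
error eps_FP,i: positive = foot further forward than predicted.

**Stage 2 — push-off correction.** Each kinetic series F of the *next* step
(combined AP ground reaction force, trailing-leg AP GRF, trailing-leg
sagittal ankle moment; forward GRF and internal plantar-flexion moment
positive) is regressed per phase on the preceding error:

    F_{i+1}(j) = beta_eps(j) * eps_FP,i + eps_{i+1}(j)

The headline quantity is the per-phase Pearson correlation r(j) (with one
predictor it carries the same information as the slope, which is reported
alongside). The full-stride view follows the push-off leg over a whole
stride: during the error's own step it is the stance leg (its kinetics fill
the pre-heel-strike phases), during the next step it is the trailing leg;
phases where it swings carry no signal and are masked. A complementary
contrast averages the kinetic curves of the k = 10 most positive and the 10
most negative errors per participant and foot.

**Group level.** Per-participant correlation curves are Fisher
r-to-z-transformed, averaged over feet within a participant (participants
stay the independent unit), and tested across participants with a 1D
statistical-parametric-mapping-style procedure: a pointwise one-sample (or
paired) t field, a cluster-forming threshold at the two-sided pointwise
alpha = 0.05 t quantile, and family-wise cluster p-values from the
sign-flip permutation distribution of the maximum cluster mass (sum of |t|
over a contiguous supra-threshold run; masked phases break contiguity).
Permutation inference was chosen over random-field-theory thresholds
because it is assumption-light and its calibration can be verified exactly
by simulation; with fewer than the requested number of distinct sign
patterns the test enumerates them exhaustively. Group means are
back-transformed with tanh.

## Event detection from the CoP butterfly

Heel strikes and toe-offs are detected from the combined center-of-pressure
trajectory alone. Every double stance is a rapid, nearly linear transfer of
the CoP from the trailing to the leading foot; between transfers the CoP
stays under the stance foot and drifts backward at belt speed. Candidate
transfers are found as supra-threshold runs of the AP CoP velocity (the
threshold is set adaptively between the bimodal slope populations, so no
amplitude threshold in physical units is needed). Each event is then
localized by least-squares lines fitted to the single-stance and transfer
segments of the *raw* AP CoP and intersecting them — heel strike at the
onset intersection, toe-off at the completion — followed by one refinement
pass that refits both lines tightly around the first-pass knees. The ML
transfer direction (plateau medians) labels the landing side; transfers
whose sides fail to alternate are resolved by dropping the weaker ramp.
Line intersection localizes knees at sub-sample accuracy even with
measurement noise of 20% of the ML butterfly amplitude, because the AP
transfer slope exceeds the stance drift by almost an order of magnitude.

## Two-window time normalization

To keep the timing of push-off aligned across steps, each step is resampled
in two sub-windows of fixed sample count: double stance (heel strike to
contralateral toe-off, default J_ds = 20 samples) and single stance
(toe-off to contralateral heel strike, default J_ss = 80), linearly
interpolated (exact on constants and ramps, no overshoot on kinetic
transients; cubic resampling is available as an option). Both sub-grids are
right-anchored — grid points cover (HS, TO] and (TO, next HS] — so j = 100%
is exactly the contralateral heel-strike sample and the heel-strike instant
belongs to one step only: the shared sample carries the *ending* step's CoM
state, which is the state the foot-placement model needs at j = 100%. Grid
sizes are configurable and recorded in output metadata.

## The synthetic generator

The generator produces exactly the statistical structure the analysis
assumes, with all ground truth retained, so every stage can be validated
without any external data:

* Heel-strike CoM-state fluctuations follow a stationary 2-state AR(1) map
  (spectral radius < 1; stationary covariance from the discrete Lyapunov
  equation). Defaults: map [[0.15, 0.05], [0.10, 0.20]], innovation SDs
  8 mm and 0.025 m/s.
* Foot placement is exactly linear in the end-of-step state plus an exactly
  Gaussian error (default sigma_fp = 10 mm; the slow-walking configuration
  uses 14 mm, slow walking being more variable). With the default
  phase-constant true coefficients (beta_pos = 1.2, beta_vel = 0.35 s)
  this yields R^2 at heel strike of ~0.6-0.7 and a de-meaned FP SD of
  ~2 cm, matching the magnitudes typical of treadmill studies.
* Within a step, the CoM fluctuation is anchored to the end-of-step state
  scaled by beta(100%)/beta(j), so the per-phase regression recovers the
  configured coefficient curves exactly in the noise-free case. Tapered
  smooth trajectory noise (zero at heel strike) makes R^2(j) rise toward
  heel strike as in real data. A consequence of end-state anchoring is a
  small (order of the placement error) discontinuity of the *absolute* CoM
  channel at heel strikes; the stance-relative position used by the
  analysis is exact.
* Kinetic channels: each leg's AP GRF and ankle moment are smooth baseline
  profiles (zero during that leg's swing; the combined GRF is the exact
  per-sample sum). The trailing leg's double-stance portion adds
  gain(j) * eps_FP of the previous step plus smooth Gaussian noise
  (Gaussian-kernel-filtered white noise, default FWHM 10% of the step, SD
  8 N for GRF and 5.5 N m for the moment). The default gain profile
  400 * (0.4 + 0.6 sin(pi u)) N/m over double stance (220 N m/m for the
  moment) gives peak expected correlations of ~0.45 (trailing GRF), ~0.41
  (moment) and ~0.33 (combined GRF) — the same order as treadmill data.
  The non-vanishing gain floor keeps the feedback active across the whole
  double stance; since the baseline tapers to zero at toe-off, the
  modulated force retains a few-newton discontinuity there, a deliberate
  realism concession.
* The closed-form target for the next-step correlation field is
  r*(j) = g(j) sigma_fp / sqrt(g(j)^2 sigma_fp^2 + sigma_noise(j)^2),
  evaluated with the same sampling and linear interpolation as the
  pipeline so that estimates converge to it as strides accumulate.
* The CoP is the spec of the detector's piecewise world: single stance
  under the stance foot with backward drift at belt speed plus a linear
  heel-to-toe roll; double stance a linear AP/ML transfer; plus broadband
  measurement noise (default SD 1 mm). Broadband (white) noise is the
  natural model for force-plate CoP jitter and is also the harder case for
  event detection than smooth noise of equal amplitude.
* Step timing is metronome-regular (the emulated protocol paced stride
  frequency); belt speed is c * sqrt(g l) with c = 0.4 (normal) or 0.2
  (slow).

What the generator does *not* emulate: step-time variability, non-Gaussian
error tails, drift or fatigue, kinematic cross-talk between channels, and
any within-stride dynamical coupling beyond the linear placement map — so
passing tests demonstrate correctness of the estimators on data satisfying
the model's assumptions, not robustness to real-data violations of them.

## Numerical choices

* Per-phase OLS is solved from the 2x2 normal equations; a predictor pair
  with determinant below 1e-12 of its scale is flagged degenerate and
  returns NaN coefficients rather than silent zeros.
* Correlations at phases whose kinetic column has (numerically) zero
  variance are masked; a zero-variance error vector raises an explicit
  error instead of propagating NaN.
* Fisher transform clips |r| = 1 to 1 - 1e-12 with a warning.
* Permutation p-values use (1 + #{null >= observed}) / (B + 1) for sampled
  sign patterns and the exact fraction for exhaustive enumeration; both
  keep the test level-accurate. Seeds are mandatory for reproducibility;
  identical configuration and seed reproduce every output byte.
* Steps whose double- or single-stance sub-window is shorter than 2
  samples, or that lack a contralateral toe-off, are dropped whole and
  logged; nothing is imputed.

## Problem sizes used in validation

The test and acceptance runs use the generator's study-scale defaults: 200
strides per trial, 200 Hz sampling, 20-participant groups, 200 replicate
null experiments with 1000 permutations for the calibration of the cluster
test, 20,000 strides for correlation-field convergence, and 100 Monte-Carlo
replicates per sample size (50/200/800 strides) for the 1/sqrt(n)
parameter-recovery scaling.

## Known limitations

* The event detector is validated against synthetic ground truth only;
  real recordings (soft-tissue artifacts, crossover steps, force-plate
  cross-talk) may need retuned smoothing and merge windows.
* The phase grid excludes the exact heel-strike instant at the step's
  start (it belongs to the preceding step's 100% point); analyses that
  need a j = 0 sample should read the preceding step's endpoint.
* Whether real CoM velocity should include belt speed is irrelevant for
  the de-meaned regressions but matters for adapters ingesting external
  data; the package consumes velocity as provided.
* Group inference averages left- and right-foot curves in z-space within a
  participant; treating feet as independent samples would roughly double
  the nominal sample size and is deliberately not done.
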