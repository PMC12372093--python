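# Methods

This note documents the models implemented in `myospring`, the choices
made where the design was genuinely open, and what the test suite does and
does not demonstrate.

## Normalization and inputs

All muscle lengths are expressed in units of the optimal length Lo (the
length at which the maximal active force Fo is produced at the maximal
alpha-motoneuron firing rate) and all forces in units of Fo.  The
activation input is the alpha-motoneuron firing rate alpha in pulses per
second (pps) on [0, 120]; 120 pps is treated as the physiological maximum.
The classic Hill-type reference models in `myospring.literature` instead
take a dimensionless normalized activation; `pps_to_normalized` divides by
120, and the two scales are never mixed implicitly.

## Evaluation Model (`myospring.evaluation`)

The intermediate model writes the isometric force as an active Gaussian
plus a passive term, saturated at zero:

    F_ISO(alpha, L) = max(0, A(alpha) exp(-((L - mu(alpha))/sigma(alpha))^2) + Fp(L))

with a rational amplitude A(alpha), a double-exponential mean mu(alpha)
(the optimal length, which shifts left with activation) and a
trigonometric width sigma(alpha).  The passive force combines a base-10
logistic between plateaus f1 and f2 (centre f4 ≈ 1.45 Lo, rate f3),
representing the steep rise toward the fibre-breaking length, with a
decaying exponential f5 exp(f6 L) that makes the passive force negative
below L = 1.  That negative branch is what gives the total force an
activation-dependent zero crossing (rest length) on the ascending limb.

The shipped coefficient tables are the package defaults.
Evaluations outside alpha in [0, 120] pps or L in [0.3, 1.8] Lo warn
rather than fail, so extraction pipelines can probe the edges.  The
Gaussian exponent is taken squared (`((L-mu)/sigma)^2`): the shapes are
described as Gaussians and the coefficient tables are consistent with
that reading.

`fit_gaussian_slice` / `fit_active_slices` recover (A, mu, sigma) from a
sampled active-force surface by per-activation nonlinear least squares
(scipy `curve_fit`, moment-based starting values).  With the default
synthetic surface (6 activation levels x 50 lengths on [0.4, 1.5] Lo,
Gaussian noise sd 0.01 Fo) recovery is well inside 2 % relative error.

## Control Model and generation pipeline (`myospring.control`)

The final model is a controllable nonlinear spring

    F_ISO(alpha, L) = K(alpha, L) (L - L0(alpha)),

with a quadratic rest length L0(alpha) and a stiffness surface K that is
cubic in alpha and sextic in L (a 4x7 coefficient matrix).  The structural
zero F_ISO(alpha, L0(alpha)) = 0 holds exactly by construction.  Negative
spring forces are clamped to zero by default (muscles cannot push); the
flag `saturate_negative` exposes the unclamped form.  The validity box is
L in [0.4, 1.5] Lo, alpha in [0, 120] pps.

**Conditioning of the printed coefficients.**  The rows of the stiffness
matrix multiplying alpha^3, alpha^2 and alpha are near-cancelling sums;
their printed rounding (4-5 decimals) is amplified by alpha^3 up to
120^3 ≈ 1.7e6, and the printed table yields negative stiffness above
roughly 50 pps.  The shipped table is therefore treated as an
illustrative default, pinned by tests only at alpha = 0 where just the
constant row contributes.  The supported quantitative path is
regeneration via the pipeline below; the oculomotor plant uses a
regenerated model by default.

**Pipeline.**  `fit_control_model` runs four steps:

1. *Rest-length extraction* — for each alpha on {0, 10, ..., 120} pps the
   ascending-limb zero crossing of the unsaturated Evaluation-Model force
   is located by scanning down from the optimal length and refined by
   bisection to 1e-10.  The descending-limb zero beyond the Gaussian tail
   is ignored as physiologically meaningless.
2. *Quadratic refit* of the rest-length points by least squares.  The
   true rest-length curve of the Evaluation Model drops sharply between 0
   and 10 pps, so the quadratic is a smoothing approximation (residual
   norm ≈ 0.1 over 13 points); the stiffness fit absorbs the remaining
   mismatch everywhere except near the rest length itself.
3. *Stiffness extraction* — equivalent stiffness K = F/(L - L0(alpha)) on
   a grid twice as dense as the rest-extraction grid (alpha step 5 pps, L
   step 0.025 Lo).  Nodes within delta = 0.02 Lo of the rest length are
   excluded: there the quotient amplifies any rest-length imperfection.
   The denser grid matters because the passive sigmoid rises steeply near
   1.45 Lo and a coarse grid leaves the fitted polynomial uncontrolled
   between nodes in that region.
4. *Capped stiffness refit* — the 28-term basis {alpha^3..1} x {L^6..1}
   (alpha scaled by 1/120 for conditioning; coefficients returned on the
   raw scale) is fitted by minimizing the squared *force* residual
   subject to a pointwise bound of 0.075 Fo on the zero-saturated force
   residual at every node, solved as a small quadratic program after QR
   preconditioning (scipy SLSQP).  Unconstrained least squares on the
   stiffness quotient concentrates error at the sigmoid wall (max force
   error ≈ 0.10 Fo); the cap trades a negligible RMS increase for a
   uniform bound.  `fit_stiffness` without a cap still performs the plain
   least-squares fit, which reproduces a noiseless polynomial surface to
   machine precision.

With default settings the regenerated spring reproduces the Evaluation
Model over the validity box with max |ΔF| ≈ 0.076 Fo and RMS ≈ 0.027 Fo
(both saturated), on the order of the spring form's intrinsic
approximation error.
A small spurious positive force (within the cap) can appear below the
rest length where the fitted stiffness changes sign; it is bounded by
0.075 Fo by construction.

## Spindle hybrid models (`myospring.spindle`)

Both afferents are first-order filters whose eigenvalue p and length-gain
path are reset when the sign regime of the length rate changes —
shortening, lengthening, or static.  The filter state x is continuous
across every jump; only the mode variables reset.  The Ia output adds a
velocity term and a dynamic fusimotor (gamma_d) term and saturates at
zero, which reproduces the classic Ia silencing during release; the II
model routes a static length pathway KL (L - Lbar) to the output whenever
its path switch is off (static/shortening), giving a tonic
length-proportional discharge.

Numerical choices:

* **Velocity deadband** eps_v = 1e-6 length-units/s interprets the
  measure-zero condition "Ldot = 0" for sampled inputs; the three regimes
  are mutually exclusive by the deadband and each jump self-disables, so
  the jump count per simulation is exactly the number of regime changes
  (plus the initializing jump) — no Zeno behaviour.
* **Exact integration.**  Between regime changes the flow is a scalar
  linear ODE driven by the piecewise-linear input; the simulator uses the
  closed-form first-order-hold exponential step per sample interval, so
  the integration error is zero at sample points and no ODE tolerance
  exists.  Event times (deadband crossings of the linear Ldot) are solved
  exactly per segment.
* **Initial condition.**  The initial mode comes from the profile's
  initial Ldot; x0 defaults to the flow equilibrium of that mode (KL*L(0)
  while lengthening, 0 otherwise).
* **Units.**  Spindle lengths are whatever the caller supplies; the II
  offset Lbar = 2.5 implies a normalization different from the muscle
  model's L/Lo, and no implicit rescaling is applied (see the coupling
  below).
* Ldot is taken from the profile when supplied (checked against finite
  differences of L, tolerating isolated corner excursions); otherwise it
  is computed by centered differences.

## Oculomotor plant (`myospring.oculomotor`)

Two antagonist muscle springs act on a damped rotational inertia
(J = 1, R = 1, beta = 20, neutral lengths 0.5, all adimensional), with
muscle lengths L1 = L10 - R theta, L2 = L20 + R theta.  Activations are
normalized pairs (a1, a2) in [0, 1] mapped to pps by x120 — the shipped
scenario (0.7, 0.2) is read as normalized because its values are below 1.
The admissible angle range keeps both lengths at or above 0.4 Lo
(|theta| <= 0.1 with the defaults); simulations warn on exit.

* `simulate` integrates with scipy RK45 (rtol 1e-8), restarting at
  schedule switches; the plant is heavily overdamped (beta/J = 20), so
  saccade-style steps settle monotonically.  Convergence near a rest
  point where the agonist goes slack is slow (effective rate ~0.1 /s);
  the equilibrium cross-validation tests integrate to t = 200 s.
* `equilibrium_angle` walks outward from theta = 0 in the direction of
  the initial torque and bisects either a sign change or — because
  saturated forces produce flat zero-torque plateaus — the boundary of
  the first plateau, which is where the damped dynamics come to rest.
* `find_isotorque_pairs` demonstrates the redundancy of the
  activation-to-torque map: the antagonist level is swept up to the
  largest value at which the target torque is still reachable and the
  agonist is solved by bracketing; returned pairs span distinct
  co-contraction levels with joint stiffness varying by far more than
  10 % at fixed torque.
* **Spindle coupling.**  Plant lengths (~0.5 Lo) sit far below the
  spindle-II working point (Lbar = 2.5), so each muscle's spindle input
  passes through an affine map L_sp = 4 L + 1 (rates scaled by 4).  The
  defaults place the neutral length at spindle coordinate 3.0, keeping
  the static II pathway strictly positive over the admissible angle
  range; `reconstruct_angle` inverts that affine chain to recover theta
  from the two static II rates, flagging saturated (zero) rates as
  unobservable.

## Synthetic data (`myospring.synthetic`)

The force-surface generator adds i.i.d. Gaussian observation noise
(default sd 0.01 Fo, the typical residual scale of force-length surface
fits at this normalization) to a model surface on a user grid; negative noisy samples are kept, as digitized
experimental data would contain them.  The stretch generator produces the
classic ramp-and-hold(-and-release) protocol with exact corner times and
an analytic piecewise-constant rate; defaults (baseline 2.0, ramp 0.5 /s
for 1 s, 2 s hold, symmetric release, 1 kHz sampling) emulate standard
spindle characterization stimuli.  All randomness flows through explicit
integer seeds.

What the synthetic data do *not* emulate: the sampling pattern of the
original cat-muscle experiments, correlated digitization error, trial-to-
trial variability of afferent discharge, or fusimotor scheduling.
Passing tests therefore show self-consistency of the fitting and
simulation machinery under the stated noise model, not agreement with any
new experimental recording.

## Problem sizes

Default problem sizes were chosen so the whole suite exercises every path
at desk scale: 13 rest-extraction roots, ~4 000 stiffness nodes, 28
fitted stiffness coefficients, 300-sample noisy surfaces for parameter
recovery, millisecond-sampled stretches of a few seconds for the
afferents, and a handful of 200 s plant integrations for equilibrium
cross-checks.

## Known limitations

* Force-velocity behaviour exists only inside the Brown reference model;
  the package's own muscle models are strictly isometric.
* Golgi tendon organ (Ib) dynamics and static fusimotor (gamma_s)
  modulation are not modeled.
* The printed stiffness table cannot be used quantitatively at high
  firing rates (conditioning note above).
* The quadratic rest-length law cannot follow the Evaluation Model's
  sharp low-activation drop; the residual is absorbed by the stiffness
  fit away from the rest length and bounded by the force cap near it.
* Spindle outputs are in arbitrary rate units; no absolute calibration
  against recorded afferent discharge is claimed.
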