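# Methods

## Model class

A kinetic scheme is a continuous-time Markov chain over channel
conformations with generator matrix Q(V): entry (i, j), i ≠ j, is the
j → i transition rate and the diagonal makes every column sum to zero, so
probability is conserved by construction. Hand-built models restrict rates
to the exponential family A·exp(±B·V) (A in ms⁻¹, B in mV⁻¹, both strictly
positive); models produced by boundary limits may carry general symbolic
rates, because lumping a fast state pair multiplies neighbouring rates by
voltage-dependent equilibrium fractions (logistic gates) that leave this
family. The observable is the open probability, possibly corrected
algebraically (the O′/O″ constructions below), and the current is
I = g·O·(V − E_rev). Units are ms, mV, µS and nA throughout (1 µS·mV =
1 nA, so no conversion factor appears in the current); conductances are
therefore numerically in µS rather than nS.

The reversal potential defaults to the K⁺ Nernst potential for 4 mM
external / 130 mM internal at 310.15 K (−93.04 mV), matching typical
bath/pipette solutions for hERG recordings at 37 °C, and is overridable
per model.

The worked system is the five-state Wang hERG scheme
C1 ↔ C2 ↔ C3 ↔ O ↔ I with 14 kinetic parameters and one conductance.

## Simulation and sensitivities

One state is eliminated through conservation (the first in declaration
order), leaving an affine system du/dt = A(V)u + b(V). The initial
condition is the steady state at the holding voltage (the protocol's value
at t = 0), computed as the one-dimensional null space of Q.

On piecewise-constant (step) protocol segments the system is
linear-time-invariant, so the default solver propagates it exactly through
the eigendecomposition of A; first-order sensitivities with respect to
log-parameters obey the forward sensitivity equations, whose solution on a
constant segment is a convolution evaluated in closed form in the
eigenbasis (divided differences of exponentials, with the confluent limit
t·e^{λt} when eigenvalues nearly coincide). Integration always restarts at
segment boundaries, so voltage steps are never smoothed over. Ramps and
ill-conditioned eigenbases fall back to a stiff ODE solver (LSODA, abs/rel
tolerance 1e-8, optional 0.1 ms maximum step); the two routes agree to
~1e-6 on the shipped models and the test suite asserts this. Evaluation
failures from extreme parameters (overflowing exponentials, rate
magnitudes beyond 1e14/ms) raise a recoverable error type so optimisers
and the geodesic integrator can back off.

Output sensitivities are assembled by the chain rule from the state
sensitivities and the analytic gradients of the observable; the
conductance column equals the output itself (the current is linear in g).
Second-order information is never integrated: the geodesic's directional
second derivative uses the central difference
A_m(v) = [y(ρ+hv) − 2y(ρ) + y(ρ−hv)]/h², in log-parameter space, with
default h = 1e-2 and a single Richardson halving check at each geodesic
start (h is halved once when A(h) and A(h/2) disagree badly).

## Protocol and schedules

The default command is a 5000 ms staircase-like step protocol (holding
−80 mV, a hyperpolarising dip, ascending/descending steps spanning −120 to
+60 mV, a long +40 mV depolarisation and a −120 mV repolarisation that
elicits a large resurgent tail). It is a documented repository constant,
chosen to explore the voltage range and time scales that constrain hERG
kinetics in a single sweep; every algorithmic result is
protocol-parameterised, and ramps are supported for user protocols. Sample
schedules are uniform over (0, T] — the known initial point is excluded —
with M = 37 points for the sensitivity metric and geodesics and M = 5000
(1 ms spacing) for calibration and eMRMS scoring. An explicit user-supplied
schedule is accepted wherever a uniform one is.

## Geodesics and limit classification

All boundary-seeking computation works in natural-log parameters
(including the conductance). The metric is g = JᵀJ; its eigenvalues span
the sloppiness spectrum and λ_min/λ_max is the reported condition ratio.
The geodesic second-order system is integrated with an adaptive RK45
stepper (rtol 1e-6); after every accepted step the smallest eigenvalue is
re-evaluated (cached with the right-hand side's Jacobian) and the run
stops at λ_min < 1e-6 (the printed default; exposed as configuration since
it occasionally needs tuning), at |log θ| > 25, at the τ budget, or at a
solver failure, returning the partial path with its termination reason.

The initial velocity is the sloppiest unit eigenvector. Its sign is
arbitrary, and both signs generally lead to genuine (different)
boundaries; the package orients it so the largest-magnitude component
points towards zero, because removal limits yield strictly simpler
submodels and most documented limits involve a vanishing parameter. If the
first attempt exhausts its budget without reducing λ_min, the opposite
sign is retried automatically. Velocity renormalisation (arc-length-style)
exists as a switch and is off by default.

A limit is read off the terminal unit velocity: a verdict requires at
least 95% of the squared-velocity mass on the implicated parameters
(one or two); for a pair, the stability of the log-ratio (same signs) or
log-product (opposite signs) over the path tail decides whether a finite
combined parameter is proposed. Anything else is reported as unclassified
with diagnostics — never guessed.

## Symbolic reduction

A classified limit is applied by substitution and symbolic limit-taking
(θ_i = c_i·t with t → ∞ for diverging parameters, 0 for vanishing ones).
If exactly one reversible state pair acquires infinite rates, the pair is
lumped: equilibrium fractions f_a, f_b weight the outgoing rates, and when
the open state is involved the fraction becomes an observable correction
(surrogate states named O′, O″, …). Diverging conductances would rescale a
state variable and are refused with an explicit "manual reduction
required" error, as are diverging parameters with no finite combination.
The reduced model is revalidated (connectivity, column sums) and must have
strictly fewer parameters.

The shipped Wang sequence applies nine documented limits (eight taken, the
ninth recorded but beyond the error threshold):

| step | limit | class | result |
|---|---|---|---|
| r0→r1 | kf, kb → ∞, φ₁ = p5/p6 | ratio (lump C2,C3) | 14 par, 4 states |
| r1→r2 | p13, φ₁ → ∞, φ₂ = p13/φ₁ | ratio | 13 par |
| r2→r3 | p14 → 0 | zero | 12 par |
| r3→r4 | p2 → 0 | zero | 11 par |
| r4→r5 | p1, p3 → ∞, φ₃ = p3/p1 | ratio (lump C23,O) | 10 par, 3 states, O = O′/(1+φ₃e^(−p₄V)) |
| r5→r6 | φ₂ → ∞, φ₃ → 0, φ₆ = φ₂φ₃ | product | 9 par, simple rates |
| r6→r7 | p10 → 0 | zero | 8 par |
| r7→r8 | p7, p9 → ∞, φ₇ = p7/p9 | ratio (lump O,I) | 7 par, 2 states, O = O″/(1+φ₇e^(p₈V)) |
| r8→r9 | p12 → 0 | zero | documented only |

The sequence is a design fixture satisfying every structural constraint of
the documented reduction (counts 15→7 one per step, states 5→2, the
printed O′/O″ corrections, p2 → 0 as the fourth limit, the 4/4/1
taxonomy); the first lump necessarily leaves a structurally redundant
prefactor combination (three parameters feeding two observable
combinations), and the immediately following ratio limit is exactly the
escape of that redundancy — which is also what a geodesic finds at a
rank-deficient metric. Intermediate revisions are derived once through
`apply_limit` and frozen as JSON; tests assert re-derivation equals the
frozen fixtures. The automatic loop (`mbamkit reduce`) may discover a
different but equally valid sequence from a given starting point, since
boundaries reached depend on the calibrated parameters and the velocity
sign convention.

Consistency of every transition is verified by embedding: the full model
is simulated with diverging parameters at 1/ε and vanishing ones at ε
(ε = 1e-1, 1e-2, 1e-3), from parameters projected off the full model's
calibrated point, and the eMRMS against the reduced model must fall
monotonically. Samples coinciding exactly with a voltage-step junction are
excluded there: a lumping limit replaces fast relaxation by an
instantaneous algebraic response, so convergence is uniform only away from
switching instants. Recalibration eMRMS keeps all samples.

## Calibration and identifiability

Fitting minimises the sum-of-squares cost over the reference's sample
times, equivalent to maximum likelihood under i.i.d. Gaussian noise.
Prefactor, conductance and combined parameters are optimised in log space
(positivity), voltage slopes in linear space. The optimiser is multi-start
bounded trust-region least squares with analytic Jacobians from the
forward sensitivities; start points are chosen by scattering 20× as many
seeded samples across the search box and refining from the best-scoring
ones, a cheap surrogate for a population-based global search. Default
bounds per class: prefactors 1e-7–1e3 ms⁻¹, slopes 1e-7–0.4 mV⁻¹,
conductance 1e-3–10 µS, combined parameters 1e-7–1e3. Failures inside a
restart yield an infinite recorded cost; all restarts are retained.

Practical identifiability is summarised as the per-parameter max/min
spread over the K lowest-cost restarts, with a spread factor below 2
counting as identifiable. The packaged study uses 16 restarts with the
best 8 compared (half, mirroring a best-30-of-50 reporting convention at
desk scale) on a reference generated from the r6 model with additive
Gaussian noise of 2% of the peak current: the r6 refit recovers all nine
parameters within a few percent with unit spreads, while the full r0 model
on the same data shows several near-equal-cost optima whose parameters
differ by orders of magnitude.

## Synthetic data

Reference traces are the clean simulation plus i.i.d. Gaussian noise per
sample (seeded, bit-reproducible). The reduction pipeline's reference is
the noiseless full-model trace; noise is used for identifiability studies,
at a default σ of 2% of the peak absolute current. The default full-model
parameter point adapts the original room-temperature values published for
this gating scheme with a 0.1524 µS conductance — a physiologically
plausible synthetic fixture, explicitly not a fit to any recording. The
generator does not emulate capacitive transients, leak, series-resistance
artefacts or filtering, so passing tests say nothing about robustness to
those features of real recordings.

## Problem sizes and numerical defaults

Geodesics use the 37-point schedule; calibration and all eMRMS scores use
1 ms sampling (5000 points). The shipped recalibration chain used 4
restarts per revision warm-started from the projection of the previous
revision's parameters; among near-optimal restarts the fixture prefers one
strictly interior to the search box, since a parameter resting on a bound
marks a non-converged estimate on a flat ridge. The identifiability study
and the acceptance recomputation use 10–16 restarts from random starts.
The recalibrated eMRMS ledger rises monotonically through the chain
(0.0025 at r1 to 0.093 at r8), with the ninth documented limit recorded as
exceeding the 0.1 acceptance threshold.

## Known limitations

- Temperature dependence (Q10), drug binding and stochastic single-channel
  behaviour are out of scope.
- The two post-lump revisions (r1, r5) have numerically rank-deficient
  metrics by construction; sloppiness condition ratios are only meaningful
  for full-rank metrics, and trend statements skip those two revisions.
- `apply_limit` covers the four documented limit patterns; genuinely new
  boundary types (e.g. diverging conductance) require manual reformulation
  and fail loudly.
- The automatic reduction loop is sensitive to the calibrated starting
  point and the sign convention for the initial geodesic velocity; the
  frozen sequence is the documented one, not necessarily the loop's output
  for arbitrary parameter fixtures.
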