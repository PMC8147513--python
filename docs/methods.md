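# Methods

This note documents the models implemented in `dbstune`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Rigidity quantification (RoMaR)

A trial is 25 s of imposed sinusoidal supination–pronation (±40°) while the
patient holds the manipulandum handle; resistive torque is digitized at
1 kHz. Processing order: low-pass filter → rectify → integrate → slope.

* **Filter.** 2-pole Butterworth, 20 Hz cutoff, applied *causally*
  (forward-only), matching real-time use; a zero-phase option
  (`zero_phase=True`) exists for offline work. A cutoff at or above Nyquist
  is rejected.
* **Window.** The first 5 s are discarded as warm-up (this also absorbs the
  causal filter transient); the following 20 s are analysed. Longer traces
  are truncated, shorter ones rejected.
* **Slope.** The angular impulse is the cumulative trapezoidal integral of
  |torque|; RoMaR is its ordinary-least-squares slope against time (units
  N·m), with the fit's RMS residual reported as a steadiness diagnostic.
  The integration and regression schemes are our choice; any consistent
  pair gives the same value up to discretization for 1 kHz data.

Useful identities used by the tests: constant torque *c* gives RoMaR = |c|;
a slow sinusoid of amplitude A gives 2A/π over whole periods; RoMaR is
positively homogeneous and sign-invariant in the torque.

## Rigidity GP

Model: y = m + f(x) + ε, f ~ GP(0, k), ε ~ N(0, σ²ₙ), with Matérn kernel

    k(r) = σ²ᶠ (1 + √3 r/ℓ) exp(−√3 r/ℓ),  r = |x − x′|,  ν = 3/2.

ν = 3/2 encodes a smooth trend with coarse data; a general-ν Gamma/Bessel
form is implemented and used as a cross-check oracle for the closed form.

* **Mean.** Constant, not learned: in a session it is frozen at the mean of
  the four seed measurements; in stand-alone fits it defaults to the data
  mean.
* **Hyperparameters.** (ℓ, σ²ᶠ, σ²ₙ) maximize the log marginal likelihood
  on log-scale with L-BFGS-B, 8 seeded multi-starts (one data-driven, the
  rest log-uniform in the bounds). Bounds: ℓ ∈ [2.5, 350] Hz, σ²ᶠ ∈
  [10⁻³, 10³]·var(y), σ²ₙ ∈ [10⁻⁴, 10]·var(y). The noise-sd floor of 1 %
  of the data sd deserves emphasis: without it, small designs with no
  repeated frequency let the likelihood collapse the noise to zero and
  interpolate measurement error, which produces spurious interior optima
  and meaninglessly narrow frequency ranges. The floor matches what
  mainstream GP-fitting tools enforce by default.
* **Numerics.** Cholesky factorization is attempted without jitter first
  (so noise-free interpolation stays exact to roundoff); on failure a
  diagonal jitter of 10⁻¹⁰·σ²ᶠ is added, escalating tenfold to 10⁻⁴·σ²ᶠ
  before a numerical-failure error. Predictive variances are floored at 0.
* **Degenerate designs.** Fitting requires observations at ≥ 2 distinct
  frequencies.

## Acquisition

Expected improvement for minimization over the observed incumbent
f(x⁻) = min yᵢ:

    u(x) = I Φ(Z) + σ φ(Z),  I = f(x⁻) − μ(x),  Z = I/σ   (σ > 0; else 0).

Candidates are the 5 Hz programmable grid up to the tolerability ceiling.
Ties break toward the lowest frequency (clinically conservative,
battery-friendly). Over-exploitation guard: if the posterior sd at the EI
argmax is below `exploration_ratio`·σₙ (ratio 0.5 by default — the point is
already known to well within measurement noise), the step is diverted to
the maximum-posterior-variance grid point and flagged. With no data the
incumbent defaults to the prior mean, making EI constant and the selection
fall to the lowest feasible frequency.

## Session protocol

Visit 1: all grid frequencies 10–185 Hz in seeded pseudorandom order,
book-ended by two measurements at the clinical frequency; an intolerable
frequency lowers the ceiling and removes every untested frequency above it.
Visit 2: four seeds (30, 80, 90, 140 Hz), mean frozen, then 8 iterations of
refit → predict → select → measure, with the current-vs-previous preference
question after every measurement from the second onward: 12 measurements,
11 choices. Hyperparameters are refit after every observation. An
intolerable proposal lowers the ceiling and re-selects *within* the same
iteration, so the measurement count is invariant. Consecutive re-tests of
the same frequency are legitimate under EI with noise; the preference
question is still asked and the resulting identical-frequency pair carries
zero likelihood information (its probit argument is identically 0).
Wash-in time (4 min per setting) is protocol metadata, not simulated; all
randomness derives from one session seed through named child streams, so a
session is bit-reproducible.

## Probit-GP preference model

Value v(x) = f(x) + ε with ε ~ N(0, σ²), σ = 1 fixed. A choice a ≻ b has
probability Φ((f(a) − f(b))/√2σ). MAP estimation maximizes the strictly
concave objective −½fᵀK⁻¹f + Σ log Φ(Zᵢ) by damped Newton–Raphson
(step-halving line search, gradient tolerance 10⁻⁸, ≤ 200 iterations),
best of 25 seeded uniform[−1, 1] restarts. Binary comparisons cannot
identify the kernel's length-constant, so the preference kernel reuses the
ℓ fitted on the same session's rigidity GP with unit signal variance.
The likelihood is translation-invariant; f_MAP is stored centered to mean
zero. Prediction: μ(x) = kᵀK⁻¹f_MAP and σ²(x) = k(x,x) − kᵀ(K + C⁻¹)⁻¹k,
where C is the likelihood's negative Hessian at the MAP; C is given a 10⁻⁸
diagonal jitter before inversion because chain comparisons leave it
singular. (The predictive mean omits C while the variance includes it; the
expressions are implemented as printed in the preference-learning
literature this follows.) The preferred frequency is the argmax of μ over
the grid, ties to the lowest frequency.

## Virtual patient

The ground-truth rigidity curve is the minimal smooth family reproducing
the qualitative features reported for akinetic-rigid patients:

    r(f) = r_off − dip·G(f; 10, w₁) + worsen·G(f; 35, w₂)
           − benefit·L((f − c)/s) + bump·G(f; 142.5, w₃)

(G unit Gaussian, L logistic). Two profiles ship:

* **ar1** — ceiling 155 Hz, no bump, broad logistic (center 70 Hz, slope
  25 Hz) so rigidity declines roughly in proportion to frequency all the
  way to the ceiling; argmin at 155 Hz.
* **ar2** — ceiling 185 Hz with a 130–155 Hz bump; argmin at 185 Hz.

Both are synthetic constructions, not fits to any recording. Measurement
noise defaults to 5 % of the curve's range (the scale of scatter visible in
quantified-rigidity data); measurements are i.i.d. given frequency
(post-wash-in rigidity treated as stationary). The preference value
function is

    v(f) = nb(f) − λ·softplus((f − f₀)/s₀),  nb = (r_off − r(f))/benefit,

with (λ, f₀, s₀) chosen per profile — analytically, from v′ = 0 — so the
peak sits at the lowest grid frequency achieving ≥ 80 % of the maximal
rigidity benefit (105 Hz for ar1, ~100 Hz for ar2), below the rigidity
argmin. Choice noise on the value axis defaults to 0.05: comparisons
between settings differing by ≥ 30 % of the value range are then nearly
deterministic while adjacent 5 Hz settings are near chance, mirroring human
pairwise-comparison reliability. Synthetic torque traces drive a 0.5 Hz,
±40° angle sinusoid through stiffness + viscous terms calibrated so the
trace's RoMaR reproduces r(f) (peak torque A solves 2A/π = r(f); viscous
fraction 0.2, torque noise 2 % of peak).

What the simulator does **not** emulate: wash-in/wash-out dynamics, motor
fluctuation and fatigue drift within a visit, tremor contamination of the
torque signal, asymmetric or heavy-tailed measurement noise, and
inconsistent (intransitive) preference behaviour. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
clinical performance.

## Evaluation

The optimal frequency is the argmin of the posterior mean on the grid (ties
to the lowest frequency). The frequency range is the set
{x : μ(x) ≤ μ_min + σ_min} with σ_min evaluated at the optimum (one-sided,
since the fitted mean cannot fall below its minimum); reported are both the
width of the contiguous interval containing the optimum (headline metric)
and the distance from the optimum down to the lowest in-range frequency.
A non-contiguous membership set is also returned.

Sampling-efficiency simulations rebuild GP predictions from subsets of a
brute-force sweep. Equal-interval selection takes n evenly spaced targets
from 10 Hz to the maximum tolerated frequency, each rounded to the nearest
tested setting with midpoints rounding up (so n = 3 on a 10–155 Hz grid
selects 10, 85, 155 Hz); random selection draws n tested frequencies
uniformly with replacement (a repeat re-uses the recorded value) over
seeded repeats, reporting mean ± sd of the width. Both reuse
*participant-level* kernel hyperparameters fitted once on the full sweep:
the comparison is meant to isolate sampling design, and per-subset refits
at n ≈ 12 without repeated frequencies are statistically degenerate. The
BayesOpt column refits per history prefix because that is what the live
session actually does; its n = 1 row (where hyperparameters are
unidentifiable) borrows the parameters of the earliest identifiable fit.

Problem sizes used throughout the validation suite: 20 seeded session
replicates for recovery and efficiency checks, 50 replicates for
length-constant recovery, 5 inner repeats per random-sampling draw, 10⁶
antithetic Monte-Carlo draws per expected-improvement check, and dense
0.05-resolution grid searches for the 3-point probit-GP MAP oracle.

## Known limitations

* One-dimensional parameter space only; the kernel API permits more but
  amplitude/pulse-width axes are untested.
* The frequency-range width at 5 % noise on the shipped profiles is a few
  grid steps, so it is quantized in 5 Hz units.
* With a gently sloping rigidity tail near the ceiling, the GP-mean argmin
  occasionally (≈ 15 % of seeded sessions on ar1) lands 15–25 Hz inside the
  ceiling; this is an identifiability limit of 12 noisy samples, not an
  acquisition failure.
* Active selection of preference queries is out of scope; the preference
  model is fitted post hoc from the fixed current-vs-previous chain.
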