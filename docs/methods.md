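# Methods

`rheoinverse` infers the molecular parameters of the single-mode Rolie-Poly
constitutive model for entangled, monodisperse polymer solutions from steady
simple-shear rheometry, using a neural-network surrogate of the
parameter → stress map and a bounded gradient-descent inverse solver.  This
note records the model, the numerical choices, and what the validation
studies do and do not demonstrate.

## Constitutive model

The conformation tensor A (normalized to the identity at equilibrium)
evolves as

    dA/dt = L·A + A·Lᵀ + f(A),

with the non-Gaussian (finitely extensible) relaxation function

    f(A) = −(1/τD)(A − I) − (2/τR) ks(λ) (1 − √(3/trA)) [A + β (trA/3)^δ (A − I)],

chain stretch λ = √(trA/3), and the FENE spring factor

    ks(λ) = [(3 − λ²/χmax²)(1 − 1/χmax²)] / [(1 − λ²/χmax²)(3 − 1/χmax²)],

which is exactly 1 at λ = 1 and diverges as λ → χmax.  The polymeric stress
is σp = G ks(λ)(A − I) with plateau modulus G = ηp/τD; the total stress adds
the Newtonian solvent contribution 2 ηs D.  In simple shear with
u = (γ̇ y, 0, 0) (so L carries γ̇ in its (x, y) slot), the observables are
the shear stress σxy = ηs γ̇ + G ks A_xy and the first normal stress
difference N1 = G ks (A_xx − A_yy); the solvent contributes nothing to N1.

Free parameters, with the default admissible box and sampling scale:

| parameter | meaning | range | scale |
|---|---|---|---|
| ηp | zero-shear polymer viscosity [Pa s] | 1–6000 | log |
| τD | reptation (disengagement) time [s] | 1–5000 | log |
| τR | Rouse (stretch) time [s] | 1–50 | log |
| χmax | maximum stretch ratio | 15–20 | linear |
| β | convective-constraint-release coefficient | 1–25 | linear |

Fixed constants: solvent viscosity ηs = 1.0 × 10⁻³ Pa s (water; the target
systems are aqueous DNA solutions) and CCR stretch exponent δ = −1/2, the
conventional single-mode choice.  Both are overridable per parameter set.
τR ≤ τD is deliberately not enforced — the admissible box allows either
ordering.  Note the wide β range: this box treats β as an effective CCR
strength that may absorb other prefactors, rather than restricting it to
the conventional [0, 1].

The zero-shear limits used as analytic anchors follow from linearizing
about A = I: σxy/γ̇ → ηs + ηp and N1/γ̇² → 2 ηp τD as γ̇ → 0.

## Steady-state solver

At steady state the planar-shear problem reduces to three unknowns
(A_xx, A_xy, A_yy): the advective term contributes 2γ̇A_xy to the xx
equation and γ̇A_yy to the xy equation, and the yy and zz equations are
identical on the physical branch so A_zz = A_yy (asserted, and verified in
tests rather than assumed).  The reduced system is solved by damped Newton
iteration with an analytic Jacobian:

* residuals are scaled by the local relaxation rate times (1 + trA), so one
  tolerance (default 1e-10, iterated toward ~1e-13) is meaningful from the
  Newtonian regime to deep shear thinning;
* steps are backtracked to keep the iterate positive definite and below the
  finite-extensibility bound trA < 3χmax²;
* converged roots with A_xy < 0 or A_yy ≈ 0 are rejected as spurious — the
  physical branch is the one continuously connected to equilibrium, and at
  high Weissenberg number Newton from a poor start can land on a
  nonphysical root;
* rate sweeps warm-start each rate from the previous one; isolated solves
  build a geometric continuation ladder from Wi ≈ 0.01; the fallback is
  stiff pseudo-time integration (LSODA) of the reduced system followed by a
  Newton polish.

The solver is vectorized two ways: across the rates of one curve (used by
the inverse solver, with the previous iterate's steady states cached as
warm starts) and across parameter sets at a fixed rate (used for bulk
training-set generation; 3000 sets × 17 rates solve in well under a
second).  Correctness is established against an independent oracle — stiff
time integration of the full-tensor evolution equation from equilibrium to
long times — which agrees to ~1e-13 relative on random parameter draws; the
acceptance suite re-checks 20 draws at 1e-6.

## Surrogate network

A fully connected tanh network with an affine output layer maps
(ηp, τD, τR, χmax, β, γ̇) to (σxy, N1).  The reference architecture is
5 hidden layers × 192 neurons.  Scaling choices (the raw quantities span up
to eight decades, so raw-space least squares would be meaningless):

* inputs ηp, τD, τR, γ̇ enter as log10, then all six features are min-max
  mapped to [−1, 1] using the declared bounds (no data-dependent input
  scaling);
* outputs are log10-transformed and standardized on the training split;
* the quality metric is always the mean relative error |σ̂ − σ|/σ in raw
  stress space, averaged over rows and both components, reported in %.

Training data are sampled uniformly on each parameter's declared scale,
labeled by the steady-state solver, and split by *parameter set* (default
proportions 10000/3000/2000) so validation measures generalization to
unseen fluids, not to unseen rates of a fluid seen in training.  A failed
steady solve (rare) causes that parameter set to be resampled; the count is
recorded on the dataset.

Training is minibatch Adam (β1 = 0.9, β2 = 0.999) with backpropagation,
implemented directly on float32 weight arrays; the loss is the batch mean
squared error plus ξ Σ w² over weights (biases unpenalized), ξ = 1e-6 by
default.  The learning rate starts near 1e-3 and halves when the
validation relative error has not improved for `lr_patience` epochs —
the late-training plateau is set by step-size jitter, so decaying the rate
lowers the attainable error floor.  Early stopping uses patience on the
same validation metric; the best-validation epoch is kept, and the best of
`n_repeats` independent runs is returned.

Studies in this repository run at a scaled-down size chosen to keep the
full suite at desk scale: 3000 parameter sets × 17 rates and a single
training repeat, which brings the 5 × 192 network to roughly 1.5–2.5%
test relative error in a few minutes on one CPU.  The full-size protocol
(15000 sets × 91 rates, ≥3 repeats, architecture scan over layer/width
grids) is supported by the same code path at proportionally higher cost.

## Inverse solver

Trial coordinates ω ∈ R⁵ map to parameters through the sigmoid
θ̂ᵢ = Minᵢ + (Maxᵢ − Minᵢ)/(1 + e^(−ωᵢ)), so every iterate is strictly
inside the admissible box.  The objective is the mean relative stress
misfit over the M rate points and both components,

    Error(ω) = (1/2M) Σⱼ Σ_c |σ̂_c(γ̇ⱼ; θ̂(ω)) − σ_c,data(γ̇ⱼ)| / σ_c,data(γ̇ⱼ).

Two backends predict σ̂: the trained surrogate (gradients by reverse-mode
differentiation through the network, the output unscaling and the sigmoid
map) and the exact steady-state solver (gradients by implicit-function-
theorem sensitivities: at the steady root R(y*, θ) = 0,
dy*/dθ = −J⁻¹ ∂R/∂θ with the Newton Jacobian J already in hand; a central
finite-difference path is retained as a cross-check).  The direct backend
decouples inverse-solver correctness from surrogate quality and is the
reference for parameter-recovery validation.

The landscape of Error(ω) has two structural hazards that shaped the
optimizer:

1. an *under-prediction plateau* — wherever σ̂ ≪ σ_data the relative error
   saturates at 1 and gradients are exponentially small;
2. a curved, narrow valley coupling ηp and τD (their admissible ranges
   span 3–4 decades, and the stress depends on them largely through
   G = ηp/τD and the Weissenberg numbers), which makes fixed-step descent
   zigzag and converge very slowly — the same two parameters converge
   slowest in the convergence benchmarks.

The update is therefore Adam-preconditioned gradient descent on ω: the
per-coordinate second-moment scaling makes one step-size schedule work
across both regimes.  Empirically, line scans from every observed stalled
iterate to the generating parameters were monotonically decreasing, i.e.
with these data the functional has no genuine spurious local minima and
stalls are optimizer artifacts; the scheme below removes them:

* ρ (the step size) decays by `rho_decay` (default 0.3) when the mean error
  over the latest `saturation_window` iterations stops improving on the
  window before it; decay is suspended while the error exceeds 0.5, since
  on the plateau progress per window is tiny and decaying there strands
  the descent mid-traverse;
* iteration stops when the ω-update max-norm falls below ε = 1e-6;
* a parameter whose true value lies *on* a box bound (e.g. β = 1 for the
  highest-concentration DNA sample) drives its coordinate toward ±∞
  forever; a coordinate drifting monotonically outward past |ω| > 8 for
  100 iterations is frozen ("pinned") at the bound.  Pinning is reversible:
  if the gradient starts pulling a pinned coordinate back inside, it is
  released.  A pinned parameter is reported at its frozen mapped value
  (within ~0.1% of range of the bound for linear-scale parameters);
* on convergence the schedule is reset (warm-restart cycle: ρ back to ρ0,
  moments zeroed) and the descent continues; the run ends when a full
  cycle fails to improve the best error by 0.1% (or after 6 cycles, which
  otherwise would recur forever when a bound parameter keeps creeping).
  Cycles rescue runs whose schedule decayed before a weakly-pulled
  coordinate (typically χmax after a plateau traverse) reached its optimum.

Restarts draw initial parameters uniformly on each parameter's sampling
scale (log for ηp, τD, τR) and invert the sigmoid map, so starts cover the
box evenly.  Aggregates (mean ± SD per parameter) pool converged restarts
only; a result in which no restart converged is flagged, not raised.  A
coordinate whose gradient stays below 1e-12 for 100 iterations is flagged
"unidentified" rather than reported as a spurious value.  Curves with
fewer than ~10 rate points trigger an identifiability warning.

On noise-free 91-rate curves generated from the four lambda-DNA reference
parameter sets, every converged restart recovers every parameter within
1% (typically ~1e-6 relative for interior parameters; ~0.7% for β pinned
at its bound), with cross-restart SDs far below 1% of the mean.

## Validation studies

**Noise robustness.** Multiplicative white noise bounded by a maximum
fractional level is applied independently to every σxy and N1 value (the
level is a hard bound on the support; a truncated-Gaussian option with
level = 2 SD exists behind a flag).  For each level, `n_realizations` noisy
curves are each inverted from `n_restarts_per_realization` random starts;
converged estimates are pooled and normalized by the pooled noise-free
(level-0) solution, making the level-0 normalized mean exactly 1 by
construction.  The acceptance suite checks, at a scaled-down protocol
(4 realizations × 4 restarts, 31-rate sweeps), for the pattern expected
from the parameter-range widths: ηp and τD (ranges two orders of
magnitude wider than the others') drifting beyond one SD of 1 at noise
levels ≥ 0.03 while τR, χmax, β stay statistically indistinguishable from
their noise-free solutions.  In the runs recorded here the measured drift
is in fact much smaller than that — normalized means stay within a few
tenths of a percent of 1 up to 3% noise, with SDs of 0.1–0.9% — because a
fully converged descent tracks the perturbed optimum of a mean-zero
bounded noise model closely; the one-SD departure pattern does not emerge
at this protocol, and the corresponding acceptance test records that
discrepancy by failing.

**Lambda-DNA round trip.** The packaged reference sets (four entangled
concentrations, 0.82–2.06 mg/mL) generate 91-rate curves; the solver
re-recovers the parameters; curves recomputed from the recovered means are
compared with the inputs (mean relative errors of σxy and N1); and ordinary
least squares of ln(value) on ln(concentration) over the four recovered
means yields the power-law exponents — ≈ 6.6 for ηp and ≈ 4.4 for τD,
consistent with concentration scaling estimated experimentally for
entangled DNA solutions.  With the direct backend this round trip is
essentially exact.  Surrogate-mediated recovery inherits the surrogate's
stress error; the residuals concentrate on τD (a few percent at ~2%
surrogate error for typical fluids) while ηp, anchored by the low-rate
viscosity asymptote, usually comes back at roughly the surrogate's own
accuracy.  Fluids near the corners of the box — in particular τD near its
lower bound with τR > τD — are genuinely weakly identifiable from steady
data alone, through the surrogate and through the exact model alike.

**Convergence benchmarks.** Random truth sets are inverted with per-
iteration error and per-parameter trajectories recorded.  Surrogate-on-
surrogate inversion (data generated by the same net) drives parameter
errors toward zero; exact-model data inverted through the surrogate leaves
residual ηp/τD errors set by surrogate accuracy.

## What the synthetic data do not show

All validation data are generated by the forward model itself (plus
bounded synthetic noise).  Passing these studies shows the inverse pipeline
is *self-consistent*: it recovers parameters of fluids that obey the model
exactly.  It does not show that a laboratory fluid obeys the single-mode
Rolie-Poly model — real steady-shear data carry polydispersity,
shear-banding and edge-fracture artifacts, instrument compliance, and
model-misspecification error, none of which are emulated here.  The
uniform multiplicative noise model is a deliberately simple stand-in for
instrument scatter; real rheometer noise is rate-dependent and correlated.
Transient protocols (start-up, cessation, oscillation) and extensional
flows are out of scope; time integration exists only as an internal
oracle/fallback.

## Degenerate inputs and tie-breaks

γ̇ = 0 returns the equilibrium state and zero stresses exactly.  Negative
rates are rejected (use the symmetry σxy odd, N1 even in γ̇).  Observed
stresses must be strictly positive for the relative-error objective.
Curves must have strictly increasing rates.  The steady solver raises a
diagnostic-carrying error only after Newton, continuation and pseudo-time
fallbacks all fail; dataset generation resamples such parameter sets and
counts them.
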