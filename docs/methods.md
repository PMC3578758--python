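# Methods

## Model and conventions

A single linear readout of N non-negative synaptic weights learns p = αN
random associations between input rate vectors x^μ (i.i.d. entries,
mean μ_x, sd σ_x) and scalar target rates z^μ (mean μ_z, sd σ_z):

    y^μ = Σ_i w_i x_i^μ − θ = z^μ,    w_i ≥ 0.

The inhibitory term θ is a *fixed* offset.  Because the mean excitatory
drive μ_x Σ_i w_i is O(√N) while the targets are O(1), feasibility pins
the total weight to Σ_i w_i ≈ θ/μ_x up to O(1); the package adopts the
convention θ = √N μ_z, i.e. the total weight is set so that a typical
weight configuration produces a mean drive √N μ_z, of which inhibition
cancels all but the target mean.  Under this convention the constraint
system, rewritten in units of the pinned mean weight, depends on the
pattern statistics only through

    B = (μ_x σ_z / (σ_x μ_z))².

B is scale-free (rates enter only through the two coefficients of
variation), vanishes for noiseless targets, and falls as the inputs
become sparser/burstier (smaller μ_x, larger σ_x) — which is why a
sparse binary input distribution, firing at the ceiling rate r_max with
probability μ_x/r_max (the maximal-variance law on [0, r_max] at fixed
mean), is capacity-optimal.

### Why θ must not track the weights exactly

An alternative reading of "inhibition cancels the mean" recomputes
θ = μ_x Σ_i w_i at every step, making the output exactly
Σ_i w_i (x_i − μ_x).  That dialect (kept as `theta_mode="mean_cancel"`)
leaves the overall weight scale completely free, and a
Farkas/function-counting argument then puts the solvability transition
at α = 1/2 for *every* target distribution: the B-dependence disappears.
We verified this numerically (transition at 0.50 for exponential targets
under exact cancellation, vs 0.391 = α_c(1) under the fixed-θ circuit).
All theory/simulation comparisons therefore use `theta_mode="fixed"`,
which is the default.

## Saddle-point equations

The capacity and error results are the replica-symmetric / zero-
temperature analysis of the convex feasibility problem
{v ≥ 0, mean(v) = 1 : (1/√N) Σ_i v_i ξ_i^μ = √B ζ^μ + ε}, with ξ, ζ
standardized pattern/target noises and ε a free offset absorbed by the
O(1) slack in the total weight.  Because the problem is convex, the
replica-symmetric answer is exact; we obtained it via the Gaussian
min-max (Gordon) route, where every order-parameter integral reduces to
the closed-form truncated Gaussian moments

    I1(κ) = κΦ(κ) + φ(κ),    I2(κ) = (1 + κ²)Φ(κ) + κφ(κ).

* **Capacity.**  α_c = Φ(κ) with κ ≤ 0 the root of B·I1(κ) + κ = 0.
  α_c(0) = 1/2, decreasing in B.
* **Weights at capacity.**  In units of the mean weight w̄:
  P(w) = F δ(w) + truncated-Gaussian(cκ, c) on w > 0, with c = 1/I1(κ)
  and F = 1 − Φ(κ).  Hence the exact relation **F = 1 − α_c**, asserted
  numerically across the B grid in the tests (with F independently
  recomputed by integrating the density).  The theory fixes only the
  shape; `wbar` is a free scale (default 1).
* **Above capacity.**  κ solves (α − I2(κ))/I1(κ)² = B.  The minimal
  per-pattern squared error, in units of the squared output-fluctuation
  scale (σ_x μ_z/μ_x)², is

      E(α, B) = (α − Φ(κ))² / (α · I1(κ)²),

  which vanishes continuously at α = α_c (the κ-equation reduces to the
  capacity equation there).  The silent fraction 1 − Φ(κ) now decreases
  with α and → 0 at large load, with the continuous part sharpening
  around a positive mean (c → 0).  `MSEResult.mse` carries the
  normalized E; `mse_physical(stats)` converts to squared rate units and
  `mse_in_sigma_z_units()` divides by B (i.e. units of σ_z²), the
  natural axis when plotting B = 1 ensembles.  Below capacity `mse` is
  exactly 0 and the silent fraction is reported as NaN: the solution
  space has positive volume there and this saddle point does not
  describe the typical solution.
* **Order parameters.**  `aux` exposes κ (the threshold location in the
  single-site problem) and c (the weight scale).  The finite
  zero-temperature combination that replaces β(Q − q) is reported as the
  response χ = c·Φ(κ) (per-site susceptibility of the projected
  solution: a fraction Φ(κ) of sites responds with gain c).
* **Noise.**  Uncorrelated Gaussian noise of variance v added to the
  *recalled* output shifts the mean squared error by exactly v; this is
  how the additivity property is implemented and tested
  (`evaluate_mse(..., noise_sd=...)`).  Noise added to the targets
  *before* learning is partially absorbed by the fit (by a factor
  1 − Φ(κ)/α) and is not the statement tested.

Validation of the transcribed system against independent finite-size
oracles (no fitted constants anywhere): solvability crossings at
N = 1000–1200 land on α_c(B) for B ∈ {0, 1/3, 0.5, 1} within finite-size
accuracy (e.g. 0.436 observed vs 0.4358 predicted at B = 0.5); the NNLS
residual matches E(α, B) for B ∈ {0, 1} over α ∈ [0.6, 1.2] within a few
trial standard deviations; the silent fraction and KS distance of the
weight law agree at N = 2000.

## Numerics

* Gaussian moments use `scipy.special.ndtr`; no quadrature is needed —
  all saddle integrals are closed forms, exact to machine precision
  (better than the 1e−12 budget the design allots them).
* Roots are always bracketed (geometric bracket expansion, then
  `brentq`, xtol 1e−14); an unbracketable root raises a diagnostic
  carrying the scanned interval.  Capacity-equation residuals are below
  1e−10 by construction.
* p = round-half-up(αN) for platform-independent pattern counts.
* NNLS is `scipy.optimize.nnls` (Lawson–Hanson active set); instances
  count as exactly solvable when the per-pattern mse < 1e−10, which
  separates feasible from infeasible by many orders of magnitude at
  N ≤ 2000.  The unconstrained baseline uses `numpy.linalg.lstsq`.
* Silent-synapse thresholds: active-set solutions have exact zeros, so
  1e−8 × (mean non-zero weight); gradient-descent weights only approach
  zero, so 1e−3 × (mean non-zero weight).
* Delta rule: default η = 0.1/(N·E[x_eff²]) (x_eff the θ-resolved
  effective input), cyclic presentation (random order behind a flag),
  weights initialized uniformly on [0, 2 μ_z/(√N μ_x)] so the initial
  drive sits at θ; a divergence guard raises once the error exceeds 10⁶
  times its initial value.  With a constant rate the rule hovers at an
  O(η) floor above capacity; a geometric anneal (γ ≈ 0.9995 per epoch)
  tracks the optimum to ~1e−5 relative error, and a 1/t schedule is also
  available.
* Determinism: every stochastic object records its integer seed; child
  seeds are drawn from a single `numpy` generator, and identical
  configurations yield bit-identical pattern sets, fits and figure CSVs.

## Synthetic data

The generator draws i.i.d. rates: exponential (unit CV, the ensemble
used in the figure simulations), sparse binary {0, r_max} (bursting
granule cells), zero-truncated Gaussian (declared moments are the
pre-truncation parameters; the realized post-truncation moments are
exposed separately and the theory consumes the declared ones), and
constant (σ_z = 0, the B = 0 ensemble).  The canonical family used by
the capacity scans pairs unit-mean exponential inputs with sparse-binary
targets of r_max = 1 + B, which realizes any B ≥ 0 exactly.  Real
parallel-fiber input is temporally structured, correlated across fibers
and non-stationary; none of that is modeled, so agreement of the tests
says the theory describes its stated i.i.d.-rate ensemble, not that it
quantitatively captures in-vivo granule-cell statistics.

## Problem sizes

Defaults are desk-scale, chosen so the full suite and the acceptance
script each run in minutes on one core: capacity scans at N = 1000 with
50 seeds, error curves at N = 1000 with 20 seeds, weight-law comparison
at N = 2000, learning-rule/oracle agreement on 20 instances at N = 150,
figures at N ≤ 1000 with ≤ 20 trials (a `--full-scale` flag enlarges
them).  Finite-size effects at these sizes are visible as an O(1/N)
upward bias of the simulated error relative to the N → ∞ theory; the
comparisons therefore use spreads across trials, not standard errors of
the mean, as the agreement scale.

## Limitations

* Replica-symmetric, zero-temperature, N → ∞ theory; exactness relies on
  convexity of the feasibility/cost problem, which holds here.
* The linear transfer function is not restrictive for the theory
  (any invertible transfer maps onto it with redefined target moments),
  but the package does not implement nonlinear transfer wrappers.
* Temporal structure (adaptive-filter generalizations, spike timing,
  climbing-fiber spiking) and other cerebellar plasticity sites are out
  of scope; the climbing-fiber interpretation of the error signal is
  documented, not simulated.
* The information measure assumes additive Gaussian readout noise.
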