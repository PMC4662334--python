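# Methods

## Model

A survey runs for `T` days over `K` single-catch traps checked and reset at
a fixed clock time daily, giving `L = T` occasions of one day. Animals hold
fixed activity centres for the survey, drawn from an inhomogeneous Poisson
process with intensity `D(x; φ)` in animals per hectare; coordinates are
planar metres. Detection follows the half-normal form
`g(d) = g0 exp(−d²/2σ²)` interpreted through the hazard link
`h(d) = −ln(1 − g(d))` per day, so the continuous-time and discrete-occasion
parameterisations describe the same process; the hazard is constant in time.

A capture removes the animal and fills the trap until the next reset. The
single-catch likelihood conditions on the *observed* availability
processes: `a_k(t)` (trap `k` empty) and `v_i(t)` (animal `i` free) are
reconstructed exactly from capture and release times, and because hazards
are time-constant every time integral reduces to a product of a hazard and
an availability total — `U_ik` (joint free/empty time for pair `i,k`) or
`A_k` (trap free time). No quadrature in time is ever needed; the totals
come from interval arithmetic (`U_ik = T − |O_k| − |H_i| + |O_k ∩ H_i|`).

The expected number of distinct captured animals,
`λ(φ,θ) = ∫ D(x) p·(x) dx`, depends on the random trap-filling history;
its exact expectation is computationally prohibitive. The estimator
plugs in the observed availability:
`λ̂ = ∫ D(x)(1 − exp(−Σ_k h_k(x) A_k)) dx`. With no captures
(`a_k ≡ 1`) this reduces to the standard λ, an identity the tests assert.
Because of the plug-in the estimator is not an exact MLE; its bias and the
coverage of its intervals are therefore assessed by simulation rather than
asserted from asymptotics.

The multicatch comparator reduces timed data to occasion histories and
maximises the standard full (Poisson-`n`) multicatch likelihood with
per-occasion competing-risks probabilities
`p_k(x) = (h_k/h·)(1 − e^{−h·})`, escape `e^{−h·}`, and
`λ = ∫ D(x)(1 − e^{−L h·(x)}) dx`. It deliberately ignores trap filling —
that is the misspecification under study.

## Geometry and units

- Trap grids place columns east–west with the westernmost column at x = 0;
  the study array is 5 × 4 at 100 m spacing (400 m east–west span).
- Integration mask: trap bounding box buffered by 4σ, regular grid at σ/4
  spacing by default, endpoint-inclusive. Detection at the mask edge is
  negligible (4σ), so the half-cell overhang of the endpoint grid does not
  affect fits.
- Reporting regions: "full" = convex hull of the traps buffered 2σ with a
  mitre join (a rectangle for rectangular arrays), "reduced" = the hull
  itself. Scenario mean densities are defined over the full region; the
  endpoint-inclusive grid at 25 m spacing reproduces the calibrated
  exponential scenario means (2.77, 1.79, 1.20, 0.92 per ha) to ±0.01.
- Densities are per hectare; mask cell areas are carried in m² and divided
  by 10⁴ inside every integral, keeping `D × cell_area` dimensionless.
- Expected population sizes use a *cell-centred* midpoint grid clipped to
  the region polygon (`integrate_intensity`), which tiles rectangles
  exactly; the endpoint-inclusive reporting grid would overstate region
  area by the boundary half-cells (≈4% on the integration rectangle), which
  matters for simulation but not for area-weighted means.

## Scenarios

Exponential scenarios calibrate `D = exp(β0 + β1 x)` so that `D(0) = DS`
(western array edge) and `D(array span + 4σ) = DMax`, giving
`β1 = ln(DMax/DS)/800 m`. Quadratic scenarios use a quadratic in x *on the
log scale* — `log D = log DMax − a (x − x_peak)²` with `a` fixed by
`D(0) = DS` — which guarantees positivity; the peak sits at the array
centre (x = 200 m) except scenario 3, whose peak is shifted to the eastern
array edge (x = 400 m). The published quadratic coefficients are not
recoverable from the endpoint summaries alone, so quadratic scenarios are
validated by endpoint calibration and parameter recovery rather than by
matching published mean densities.

## Simulator

The survey simulator is a forward-in-time competing-risks sampler. Within
an occasion the state is the set of free animals and empty traps; the next
event time is exponential with the superposed rate
`Σ_free Σ_empty h_k(x_i)`, the animal is drawn multinomially by its total
hazard and the trap by relative hazard within the animal's row. This is
distributionally identical to drawing a waiting time per animal and keeping
the minimum (exponential superposition), but needs far fewer draws; the
literal per-animal scheme ships as `simulate_survey_reference` and the two
are cross-validated in distribution. Boundaries belong to the new occasion
(half-open `[capture, release)` intervals); floating-point time ties have
probability zero and would be broken by draw order. Populations are drawn
by Poisson count plus rejection sampling against the exact intensity.

At the study design (500 replicates), the simulator reproduces the
scenario summary statistics: mean unique individuals ≈ 65/50/36/32 and
trap saturation ≈ 94/80/63/59% for the four exponential scenarios.

## Estimation and inference

- Transformed scale: logit `g0`, log σ; density coefficients are already
  log-scale and enter linearly, with gradient coefficients rescaled to
  per-hectometre units (×100 for linear, ×10⁴ for quadratic terms) so all
  optimised parameters are O(1) and finite-difference steps are
  well-conditioned.
- Start values: intercept from `n/area`, `g0` from captures/(nL), σ at half
  the median inter-trap distance; alternates (doubled σ, reduced `g0`) are
  fallbacks used only if the first start fails — on these likelihoods all
  starts reach the same optimum, which the suite spot-checks.
- L-BFGS-B with relative tolerance 1e−8; covariance is the inverse
  central-difference Hessian (step 1e−4 on the transformed scale, widening
  to 1e−3/5e−3 if not positive definite).
- Derived mean densities over a reporting region use the delta method
  through a numerical gradient and log-scale Wald intervals; `g0` and σ
  intervals back-transform from the fitting scale; the slope interval is on
  the identity scale.
- Replicate exclusion in studies: fits that fail to converge, lack a valid
  covariance, have negative variances, or have any transformed-scale SE
  above 10 are dropped and counted, mirroring the usual "did not converge
  or estimated very large variances" rule.

## Performance metrics

Relative bias is `100 (mean − truth)/truth` with Monte-Carlo SE
`100 sd/(√R |truth|)`. Surface metrics on a region grid of `M` cells with
truth `D_m`: `MSPE_r = (1/M) Σ_m (D̂_mr − D_m)² · cell_area` and
`RMSPE = (1/R) Σ_r √MSPE_r` (SE = sd of the per-replicate roots / √R);
`RMSB = √((1/M) Σ_m (D̄̂_m − D_m)² · cell_area)` with a bootstrap SE over
replicates (1000 resamples by default; the resample count is a package
default, not a published value). Truth surfaces are evaluated on the same
grids as the estimates. Per-replicate seeds are `base_seed + index`, so
results are reproducible and order-invariant.

## Problem sizes in the shipped checks

The full published study uses 500 fitted replicates per cell. The packaged
checks scale fitted-replicate counts to desk scale and widen tolerances by
`√(500/R)` accordingly: simulation-only summaries run at R = 500,
multicatch-bias checks at R = 60 (tests) and R = 100 (the acceptance
script), and single-catch recovery and coverage at R = 48. Coverage checks
use a binomial tolerance at the realised replicate count. These sizes were
fixed from the cost of one fit (~2.5 s on one core) before inspecting
outcomes.

## What the simulations do and do not show

The generator implements the study's own data-generating process: fixed
activity centres, half-normal hazard constant in time, perfect daily
resets, no behavioural response, no movement, no trap failure, and the
correct density form supplied to both estimators. Passing recovery and
coverage checks therefore demonstrates internal consistency of estimator
and simulator under these assumptions — not robustness to transients,
misspecified density forms, trap-shy or trap-happy animals, or latent
capture times (a likelihood without observed times remains intractable).
Behavioural-response hazards and clustered (Neyman–Scott) populations are
out of scope.

## Known limitations

- The plug-in λ̂ makes the estimator approximately, not exactly, an MLE;
  small positive bias in derived mean density (a few percent at 5
  occasions, shrinking at 10) is expected and observed.
- Wald intervals rely on the observed information; with very few captures
  the Hessian can be ill-conditioned and such fits are flagged rather than
  silently reported.
- Mask-based integration is exact only up to grid resolution; σ/4 keeps
  quadrature error well below simulation noise (halving the spacing moves
  reported means by far less than one Monte-Carlo SE).
- Irregular trap layouts are supported by the data model, but scenario
  builders and design tooling cover rectangular grids only.
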