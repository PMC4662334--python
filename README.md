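# ctsecr

Continuous-time spatially explicit capture–recapture (SECR) for
**single-catch traps** with observed capture times.

## The problem

Live-trapping studies of small mammals mostly use single-catch traps: a trap
holds one animal and is out of action until the next reset. Animals therefore
compete for traps, and the standard SECR likelihood for multicatch traps —
which assumes traps never fill — is misspecified for such data. In practice
the multicatch estimator is used anyway; it is surprisingly robust for
average density but badly underestimates the detection-function height `g0`
and flattens spatial density gradients, and its performance deteriorates as
trap saturation rises.

When traps record capture *times*, a tractable likelihood becomes available.
`ctsecr` implements that continuous-time estimator, the discrete multicatch
comparator, a forward-in-time competing-risks survey simulator, and a
simulation-study harness for evaluating both.

## The model

Animals have fixed activity centres `x_i` distributed as an inhomogeneous
Poisson process with intensity `D(x; φ)` (animals/ha; constant, log-linear or
log-quadratic in the east coordinate). A trap at distance `d` exposes a free
animal to the constant hazard

    h(d) = −ln(1 − g(d)),     g(d) = g0 · exp(−d² / 2σ²),

so that one 24-h occasion with a lone, always-available trap captures with
probability exactly `g(d)` — the link that lets both estimators fit the same
half-normal detection function. Captures remove both animal and trap from
the risk set until the daily reset. With availability indicators `a_k(t)`
(trap `k` empty) and `v_i(t)` (animal `i` free), observed times make the
likelihood

    L(φ, θ) = e^{−λ̂}/n! · ∏_i ∫_A D(x; φ) · exp(−Σ_k h_k(x) U_ik) · ∏_k h_k(x)^{ω_ik} dx

tractable, where `U_ik = ∫ v_i a_k dt` and
`λ̂ = ∫ D(x)(1 − exp(−Σ_k h_k(x) A_k)) dx` plugs the observed trap
availability `A_k = ∫ a_k dt` into the expected number of distinct captures.
All spatial integrals are evaluated on a habitat mask (4σ buffer, σ/4
spacing by default); maximisation is quasi-Newton on transformed scales with
observed-information Wald intervals and delta-method derived densities.

## Worked example

`examples/02_simulate_and_fit.py` simulates one five-occasion survey from a
calibrated exponential-gradient scenario (20 traps, 100 m spacing, g0 = 0.2,
σ = 100 m) and fits both estimators:

```
population 134, captured 32 individuals (67 captures), saturation 67%
trap availability A_k ranges 1.27-5.00 of T = 5 days
single-catch: g0 0.195 (0.125-0.290)  sigma 111 m  slope 1.03e-03/m  D_F 0.79 (0.49-1.26) /ha
multicatch  : g0 0.128 (0.082-0.193)  sigma 114 m  slope 9.43e-04/m  D_F 0.76 (0.46-1.24) /ha
truth       : g0 0.200  sigma 100 m  slope 1.37e-03/m  D_F 0.93 /ha
```

At 67% saturation the single-catch estimator recovers `g0` (0.195 vs 0.200,
truth inside the 95% interval) while the multicatch comparator—blind to
trap filling—compensates by collapsing `g0` to 0.128. Both recover σ; mean
density `D_F` over the hull + 2σ region is similar for the two. The other
examples calibrate the scenario surfaces (`01_calibrate_scenarios.py`) and
run a miniature parameter-recovery study (`03_recovery_study.py`).

A thin CLI wraps the same functions: `ctsecr simulate`, `ctsecr fit-sc`,
`ctsecr fit-mc`, `ctsecr study`, `ctsecr fixtures` (see `--help`).

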