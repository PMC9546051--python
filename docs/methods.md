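# Methods

## Model and assumptions

Each subject carries a latent failure ("patience") time `T` with density `f`
and cdf `F`, and a latent censoring ("waiting") time `W` with density `g`.
`T ⟂ W`, and more strongly the pair `(Y*, T)` is independent of `W`, where
`Y* ~ Bernoulli(q(T))` is the announcement decision and
`q(t) = P(Y=1 | T=t)` is an unknown function that is never estimated here.
The observables per subject are `U = YT + (1−Y)W`, `Δ = 1{T<W}`, and
`Y = Y*Δ` (an announcement can only be seen if the subject abandons first).
This yields three categories — served (`Δ=0`), announced abandonment
(`Δ=Y=1`), silent abandonment (`Δ=1, Y=0`) — and the sub-stochastic
densities

```
h1(t) = g(t)F̄(t),   h2(t) = q(t)f(t)Ḡ(t),   h3(t) = g(t)∫₀ᵗ(1−q(x))f(x)dx.
```

Exact ties `T = W` are classified as served (`Δ = 1{T<W}` taken literally);
they have probability zero under the continuous families supported here.
Dependent `(T, W)` is out of scope — the case-study remedy is stratification,
which the I/O layer and CLI support directly.

## Semiparametric estimator

Stage 1 maximizes the `γ` factor of the full likelihood — an ordinary
right-censored parametric likelihood for `W` (observed in categories 1 and 3,
censored at the announced `T` in category 2). Stage 2 maximizes the
category-1 partial likelihood in `θ` with `γ̂` plugged in; the factor
`g(Uᵢ;γ̂)` is constant in `θ` and drops out. Both stages are `q`-free.

Numerical choices:

* Exponential closed forms (`γ̂ = (n−ΣΔY)/ΣU`, `θ̂ = n₁/Σ_{Δ=0}U − γ̂`) are
  used whenever the relevant family is exponential. `θ̂` is **not truncated
  at zero**: the small-sample sampling distribution crosses zero, and the
  untruncated estimator is what the comparison study uses (fitted survival
  above 1 is flagged with a warning; `survival_curve(..., clip=True)` and
  `fit_nonparam(..., clip=True)` give the clipped practical mode).
* The general path maximizes the log-objective over log-parameters
  (positivity by construction) with Nelder–Mead from three starts (the
  template parameters scaled by 1/2, 1, 2); disagreement between starts
  surfaces as a non-converged flag. One-parameter fits use `xatol=1e-12`
  (needed for closed-form equivalence to 1e-6); multi-parameter fits use
  `xatol=1e-7` for speed.
* The normalizer `∫ g F̄` is `γ/(γ+θ)` in the double-exponential case and
  adaptive quadrature (`scipy.integrate.quad`, tolerances 1e-10) otherwise.
* Standard errors: nonparametric bootstrap of the triplets (default B=200),
  refitting both stages per resample. Model-based asymptotic covariances are
  not implemented.

A practical identifiability note: the partial likelihood learns `θ` only
through `F̄` on the support of the *served* times. When the censoring scale
is far below the failure scale (as in the study settings, 2 h vs 16 h), a
two-parameter family like the Weibull is weakly identified from category-1
data alone — the likelihood has a long flat ridge. The exponential fit, and
the test exercising Weibull recovery, respect this by construction.

## Nonparametric estimator

Ingredients of the plug-in identity (see README):

* `p̂₁, p̂₃` — empirical category frequencies (root-n consistent).
* `r̂₁, r̂₃` — Gaussian KDEs of the served/silent observed times, reflected
  at 0 (nonnegative support, no boundary halving), bandwidth by Silverman's
  rule `0.9·min(sd, IQR/1.34)·m^(−1/5)` per category unless supplied. The
  smoothness theory behind the estimator's rate does not pin a bandwidth;
  Silverman is the package's default choice.
* `Â = 1 − exp(−D̂)` with `D̂(t) = Σ_{announced Uᵢ≤t} 1/(n·Ŷ(Uᵢ))`,
  `Ŷ(t) = n⁻¹Σ1{Uⱼ ≥ t}`. The risk set is closed at `t`, so the jumping
  observation sits in its own risk set and every jump is finite; tied
  announced times contribute separate jumps at the common risk-set size.
  With `q ≡ 1` this reduces exactly to one-minus-exp of the Nelson–Aalen
  cumulative hazard of `T` right-censored by `W` (verified in tests against
  lifelines).
* Degenerate denominator (both density terms below 1e-12): the last
  well-defined ratio is carried forward (0 at the origin).
* Monotonization by running maximum; idempotent, pointwise ≥ the raw curve.
* Evaluation grid: 512 equally spaced points on `[0, τ]`;
  `τ = 0.95` empirical quantile of `U` by default (`tau_quantile`
  configurable, `1.0` = max observed time). Beyond `τ` the estimate is held
  constant at `F̂(τ)`.

## Synthetic-data generator

`simulate` draws `T`, then `W`, then the announcement uniforms from a single
seeded `numpy` Generator (fixed order, so runs are bit-reproducible given the
seed and library versions). Defaults reproduce the study conditions: Setting
1 `T ~ Exp(mean 16 h)`, Setting 2 `T ~ Weibull(scale 16, shape 1.5)`, both
with `W ~ Exp(mean 2 h)` and `q(t) = exp(−t)` with `t` in hours (the
decaying-q convention; rising and constant variants are provided). What the
generator does *not* emulate: arrival processes or queueing dynamics,
covariates, dependence between `T` and `W`, and discrete/rounded time
recording — so passing tests demonstrate correctness under the stated
sampling model, not robustness to those real-data features.

`category_probabilities` and `subdensities` evaluate the sub-density
integrals by adaptive quadrature (absolute tolerance 1e-10) and enforce
`p₁+p₂+p₃ = 1` to 1e-6; they serve as oracles for the simulator and both
estimators.

## Accuracy metric and the comparison harness

The metric is the true-density-weighted integrated squared error
`MSE(F̄̂) = ∫ (F̄̂ − F̄₀)² f₀ dt`, computed two ways: adaptive quadrature
against `f₀` (dense trapezoid on the grid body plus quadrature on the
constant-extension tail for gridded estimates), and quasi-Monte-Carlo over
1e5 scrambled-Sobol draws from `f₀`. The two routes agree to ~1e-4 on smooth
estimates and are cross-checked in tests. An untruncated exponential `θ̂ ≤
−θ₀/2` makes the integral diverge under an exponential truth; such
replicates are excluded from a cell with the exclusion count reported.

`run_table1` runs 100 replicates per (setting, n) cell at
n ∈ {100, 200, 500, 1000, 2000}, fitting both estimators on the same sample.
Per-replicate child seeds are spawned deterministically from the master seed.
Summaries report mean/median/sample-sd (n−1; NaN for a single replicate).

**Harness τ choice.** The harness evaluates the nonparametric estimator with
`tau_quantile = 1.0` (τ = max observed time) rather than the fit default
0.95. The reason is structural: `U` is dominated by the waiting time (mean
2 h) while the metric weights by the failure density (mean 16 h), so
truncating at the 0.95 `U`-quantile (≈ 6 h) would leave roughly 70% of the
metric's mass to the constant extension and impose an error floor of about
`F̄₀(τ)³/3 ≈ 0.17` that no sample size can reduce. With τ = max(U) the
measured error decreases in n, as consistency requires.

Problem sizes used by the packaged reproduction script: 100 replicates per
cell at n ∈ {1000, 2000}, both settings and estimators (about half a minute
on one CPU); the test suite runs the full five-size grid once.

## Known limitations

* No confidence bands for the nonparametric curve and no analytic asymptotic
  covariances for the semiparametric one (bootstrap only).
* `q(t)` itself is not estimable within this design and is not estimated.
* Kernel estimates in the far right tail of `U` rest on very few
  observations; the monotonized curve inherits that noise, which dominates
  its integrated error under the study conditions.
* The announcement function's time argument follows the simulation unit
  (hours by default); a constant-q model is unit-free, the exponential forms
  are not.
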