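# triplecens

Estimation of a failure-time distribution from survival data that mix
**three** observation types: right-censored, exactly observed, and
left-censored.

The motivating application is customer patience in service systems — e.g.
patients waiting for treatment in an emergency department. Each subject has a
latent *patience time* `T ~ F` (how long they are willing to wait) and an
independent *waiting time* `W ~ G` (how long until service would be offered).
Three things can happen:

1. **Served** (`Δ=0, Y=0`): service arrives first; `U = W` and `T` is
   right-censored at `W`.
2. **Announced abandonment** (`Δ=1, Y=1`): the subject leaves and says so;
   `U = T` is observed exactly.
3. **Silent abandonment** (`Δ=1, Y=0`): the subject leaves unnoticed; their
   absence is only discovered at the service call, so `U = W` and `T` is
   left-censored at `W`.

Whether an abandonment is announced is governed by an unknown announcement
probability `q(t) = P(Y=1 | T=t)`. The same structure arises in disease
screening with self-detection (symptomatic detection = announced; negative
screen = right-censored; positive screen = left-censored).

The package provides two estimators of `F` that need **no knowledge of
`q`**, a synthetic-data generator with analytic oracles, a Monte-Carlo
comparison harness, and a small CLI.

## The estimators

**Semiparametric.** With parametric families `g(·;γ)` and `f(·;θ)`, the
likelihood factor in `γ` is an ordinary right-censored likelihood
(`W` is observed for categories 1 and 3, censored at `U` for category 2),
maximized on its own. `θ` then maximizes the *partial* likelihood of the
served category,

```
ℓ(θ) = Σ_{i: Δᵢ=0} log F̄(Uᵢ;θ) − n₁ log ∫ g(s;γ̂) F̄(s;θ) ds ,
```

which is free of `q`. For exponential families both maximizers are closed
form: `γ̂ = (n − ΣΔᵢYᵢ)/ΣUᵢ` and `θ̂ = Σ(1−Δᵢ)/Σ(1−Δᵢ)Uᵢ − γ̂`
(deliberately not truncated at zero).

**Nonparametric.** Writing `p₁ = P(W≤T)`, `p₃ = P(Y=0, T<W)`, `r₁, r₃` for
the conditional densities of `U` within the served/silent categories, and
`A(t) = ∫₀ᵗ q f`, the identity

```
F(t) = [p₃ r₃(t) + p₁ r₁(t) A(t)] / [p₃ r₃(t) + p₁ r₁(t)]
```

is estimated by plugging in empirical frequencies, reflected-Gaussian kernel
density estimates, and `Â(t) = 1 − exp(−Σ_{announced Uᵢ≤t} 1/(n Ŷ(Uᵢ)))` — a
jump-sum estimator with the same algebra as one-minus-exp of a Nelson–Aalen
cumulative hazard. The resulting curve is made monotone by a running maximum
(cumulative sup).

## Worked example

```python
import numpy as np
from triplecens import (SimulationSetting, simulate, category_counts,
                        ParametricFamily, fit, fit_nonparam, mse)

setting = SimulationSetting.setting1(n=2000, seed=11)   # T~Exp(16 h), W~Exp(2 h), q=exp(-t)
sample = simulate(setting)
print(category_counts(sample).percentages(1))           # (88.4, 4.2, 7.4)

exp1 = ParametricFamily.exponential(rate=1.0)
res = fit(sample, exp1, exp1, bootstrap=200, seed=1)
print(res.gamma_hat[0], res.theta_hat[0])               # 0.5022, 0.0614

npf = fit_nonparam(sample, tau_quantile=1.0)
for t in (1.0, 4.0, 16.0):
    print(t, np.exp(-res.theta_hat[0] * t), float(npf.survival(t)))
```

prints, with the true values `exp(-t/16)` in parentheses:

```
t= 1.0   semi 0.940   nonpar 0.933   (0.939)
t= 4.0   semi 0.782   nonpar 0.798   (0.779)
t=16.0   semi 0.374   nonpar 0.201   (0.368)
```

The waiting-time rate is recovered almost exactly (0.5022 vs 1/2, bootstrap
SE 0.011) and the patience rate closely (0.0614 vs 1/16 = 0.0625, SE 0.007).
The nonparametric curve tracks the truth where data are dense and degrades in
the sparse right tail — the integrated squared errors against the true
density are 0.00002 (semiparametric) and 0.018 (nonparametric) here.

The same fits run from the shell:

```
triplecens simulate --setting 1 --n 2000 --seed 11 --out runs/sim
triplecens fit --input runs/sim/data.csv --out runs/fit
triplecens table1 --reps 100 --seed 0 --out runs/table1
```

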