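"""Semiparametric estimation of the failure-time parameter.

The full likelihood of the observed triplets factorizes into a piece that
depends only on the censoring-time parameter γ,

    L_γ = ∏ᵢ g(Uᵢ; γ)^{1-ΔᵢYᵢ} Ḡ(Uᵢ; γ)^{ΔᵢYᵢ},

because the censoring time W is observed for the served and silent categories
and right-censored at the announced failure time for the announced category.
γ̂ maximizes this piece and is free of both θ and the announcement function q.

θ is then estimated from the *partial* likelihood of the served (category-1)
observations,

    ℓ_partial(θ) = Σ_{i: Δᵢ=0} log F̄(Uᵢ; θ) - n₁ log ∫₀^∞ g(s; γ̂) F̄(s; θ) ds,

which also avoids q entirely. When both families are exponential the
maximizers are available in closed form:

    γ̂ = (n - ΣΔᵢYᵢ) / ΣUᵢ,
    θ̂ = Σ(1-Δᵢ) / Σ(1-Δᵢ)Uᵢ - γ̂.

The closed-form θ̂ is deliberately *not* truncated at zero — small samples can
produce negative estimates, in which case the fitted survival exceeds 1 and a
warning is attached; a clipped practical mode is available via
``survival_curve(..., clip=True)``. Analytic asymptotic covariances are not
implemented; a nonparametric bootstrap (resampling triplets) provides
standard errors instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize

from .data_model import SampleData
from .families import ParametricFamily

__all__ = [
    "FitResult",
    "SemiparamFit",
    "gamma_loglik",
    "theta_partial_loglik",
    "fit_gamma",
    "fit_theta_partial",
    "fit",
    "survival_curve",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-12, limit=200)
_MULTISTART_FACTORS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class FitResult:
    """One maximized objective: parameter vector, value, diagnostics."""

    params: np.ndarray
    loglik: float
    converged: bool
    method: str


@dataclass
class SemiparamFit:
    """Joint semiparametric fit (γ̂ for the censoring family, θ̂ for the failure family)."""

    gamma_hat: np.ndarray
    theta_hat: np.ndarray
    loglik_gamma: float
    partial_loglik_theta: float
    converged_gamma: bool
    converged_theta: bool
    t_family_name: str
    w_family_name: str
    n_boot: int = 0
    se_gamma: Optional[np.ndarray] = None
    se_theta: Optional[np.ndarray] = None

    def summary(self) -> dict:
        out = {
            "gamma_hat": np.asarray(self.gamma_hat).tolist(),
            "theta_hat": np.asarray(self.theta_hat).tolist(),
            "loglik_gamma": self.loglik_gamma,
            "partial_loglik_theta": self.partial_loglik_theta,
            "converged": bool(self.converged_gamma and self.converged_theta),
            "t_family": self.t_family_name,
            "w_family": self.w_family_name,
            "n_boot": self.n_boot,
        }
        if self.se_gamma is not None:
            out["se_gamma"] = np.asarray(self.se_gamma).tolist()
            out["se_theta"] = np.asarray(self.se_theta).tolist()
        return out


# ---------------------------------------------------------------------------
# objectives


def gamma_loglik(data: SampleData, w_family: ParametricFamily) -> float:
    """γ-dependent factor of the full log-likelihood at ``w_family``'s parameters."""
    dy = data.delta * data.y
    with np.errstate(divide="ignore"):
        terms = np.where(dy == 1, w_family.log_survival(data.u), w_family.logpdf(data.u))
    return float(terms.sum())


def _partial_normalizer(w_family: ParametricFamily, t_family: ParametricFamily) -> float:
    """∫₀^∞ g(s; γ) F̄(s; θ) ds — closed form for exponential/exponential."""
    if w_family.name == "exponential" and t_family.name == "exponential":
        gam, theta = w_family.params[0], t_family.params[0]
        return gam / (gam + theta)
    val, _ = integrate.quad(
        lambda s: w_family.pdf(s) * t_family.survival(s), 0.0, np.inf,
        epsabs=1e-10, epsrel=1e-10, limit=100,
    )
    return val


def theta_partial_loglik(data: SampleData, t_family: ParametricFamily, w_family: ParametricFamily) -> float:
    """Category-1 partial log-likelihood, up to θ-free additive constants."""
    served = data.delta == 0
    n1 = int(served.sum())
    if n1 == 0:
        raise ValueError("no served (category-1) observations; partial likelihood is empty")
    norm = _partial_normalizer(w_family, t_family)
    if norm <= 0:
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(t_family.log_survival(data.u[served]).sum() - n1 * np.log(norm))


# ---------------------------------------------------------------------------
# numerical maximization (log-parameter transform, multi-start)


def _maximize(objective, template: ParametricFamily) -> FitResult:
    base = np.log(np.asarray(template.params, dtype=float))
    # single-parameter families get the tight tolerances needed for
    # closed-form equivalence; multi-parameter fits trade precision for speed
    if base.size == 1:
        options = dict(xatol=1e-12, fatol=1e-14, maxiter=5000, maxfev=10000)
    else:
        options = dict(xatol=1e-7, fatol=1e-9, maxiter=2000, maxfev=4000)

    def neg(logp: np.ndarray) -> float:
        try:
            val = objective(template.with_vector(np.exp(logp)))
        except (ValueError, FloatingPointError):
            return np.inf
        return -val if np.isfinite(val) else np.inf

    best = None
    any_ok = False
    for fac in _MULTISTART_FACTORS:
        x0 = base + np.log(fac)
        res = optimize.minimize(neg, x0, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("likelihood maximization failed from every start")
    params = np.exp(best.x)
    return FitResult(params=params, loglik=-float(best.fun), converged=bool(any_ok), method="nelder-mead(log)")


# ---------------------------------------------------------------------------
# estimators


def fit_gamma(data: SampleData, w_family: ParametricFamily, method: str = "auto") -> FitResult:
    """Maximize the γ factor of the full likelihood.

    ``method``: "auto" (closed form when available), "closed_form", "numeric".
    """
    if data.u.sum() <= 0:
        raise ValueError("degenerate sample: all observed times are zero")
    use_closed = w_family.name == "exponential" and method in ("auto", "closed_form")
    if method == "closed_form" and w_family.name != "exponential":
        raise ValueError("closed-form gamma estimator requires an exponential censoring family")
    if use_closed:
        dy = data.delta * data.y
        gamma = (data.n - dy.sum()) / data.u.sum()
        fam = w_family.with_vector([gamma])
        return FitResult(np.array([gamma]), gamma_loglik(data, fam), True, "closed_form")
    return _maximize(lambda fam: gamma_loglik(data, fam), w_family)


def fit_theta_partial(
    data: SampleData,
    t_family: ParametricFamily,
    gamma_hat,
    w_family: ParametricFamily,
    method: str = "auto",
) -> FitResult:
    """Maximize the category-1 partial likelihood at the plugged-in γ̂.

    The exponential/exponential closed form may return a negative θ̂ (no
    truncation); the numeric path enforces positivity through a log transform.
    """
    served = data.delta == 0
    n1 = int(served.sum())
    if n1 == 0:
        raise ValueError("no served (category-1) observations")
    gamma_hat = np.atleast_1d(np.asarray(gamma_hat, dtype=float))
    w_fitted = w_family.with_vector(gamma_hat)
    both_exp = t_family.name == "exponential" and w_family.name == "exponential"
    if method == "closed_form" and not both_exp:
        raise ValueError("closed-form theta estimator requires exponential families for T and W")
    if both_exp and method in ("auto", "closed_form"):
        su = data.u[served].sum()
        if su <= 0:
            raise ValueError("degenerate sample: served observation times sum to zero")
        theta = n1 / su - gamma_hat[0]
        if theta > 0:
            ll = theta_partial_loglik(data, t_family.with_vector([theta]), w_fitted)
        else:  # outside the family's parameter box; objective evaluated directly
            ll = float(-theta * data.u[served].sum() - n1 * np.log(gamma_hat[0] / (gamma_hat[0] + theta)))
        return FitResult(np.array([theta]), ll, True, "closed_form")
    return _maximize(lambda fam: theta_partial_loglik(data, fam, w_fitted), t_family)


def fit(
    data: SampleData,
    t_family: ParametricFamily,
    w_family: ParametricFamily,
    bootstrap: int = 0,
    seed: Optional[int] = None,
    method: str = "auto",
) -> SemiparamFit:
    """Compose ``fit_gamma`` and ``fit_theta_partial``; optional bootstrap SEs.

    The bootstrap resamples triplets with replacement and refits both stages;
    it stands in for the model-based asymptotic covariances.
    """
    gfit = fit_gamma(data, w_family, method=method)
    tfit = fit_theta_partial(data, t_family, gfit.params, w_family, method=method)
    out = SemiparamFit(
        gamma_hat=gfit.params,
        theta_hat=tfit.params,
        loglik_gamma=gfit.loglik,
        partial_loglik_theta=tfit.loglik,
        converged_gamma=gfit.converged,
        converged_theta=tfit.converged,
        t_family_name=t_family.name,
        w_family_name=w_family.name,
    )
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        gammas, thetas = [], []
        for _ in range(bootstrap):
            boot = data.resample(rng)
            try:
                gb = fit_gamma(boot, w_family, method=method)
                tb = fit_theta_partial(boot, t_family, gb.params, w_family, method=method)
            except (ValueError, RuntimeError):
                continue  # degenerate resample (e.g. no served observations)
            gammas.append(gb.params)
            thetas.append(tb.params)
        if len(gammas) >= 2:
            out.n_boot = len(gammas)
            out.se_gamma = np.std(np.vstack(gammas), axis=0, ddof=1)
            out.se_theta = np.std(np.vstack(thetas), axis=0, ddof=1)
    return out


def survival_curve(fit_result: SemiparamFit, t_family: ParametricFamily, grid, clip: bool = False) -> np.ndarray:
    """Fitted failure-time survival F̄(t; θ̂) on a grid.

    Values are not clipped to [0, 1] by default: a negative exponential θ̂
    yields values above 1, which are flagged with a warning (pass
    ``clip=True`` for the practical mode).
    """
    grid = np.asarray(grid, dtype=float)
    theta = np.atleast_1d(np.asarray(fit_result.theta_hat, dtype=float))
    if fit_result.t_family_name == "exponential":
        values = np.exp(-theta[0] * grid)  # valid for any real θ̂, including ≤ 0
    else:
        values = t_family.with_vector(theta).survival(grid)
    if not clip and np.any(values > 1.0):
        warnings.warn(
            "fitted survival exceeds 1 (negative rate estimate); use clip=True for the practical mode",
            UserWarning,
            stacklevel=2,
        )
    return np.clip(values, 0.0, 1.0) if clip else values
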