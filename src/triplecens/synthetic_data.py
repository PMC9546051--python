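"""Simulator for (U, Y, Δ) triplets and the analytic category-level oracles.

The generative model: a latent failure (patience) time ``T ~ f`` and an
independent censoring (waiting) time ``W ~ g``; an announcement decision
``Y* ~ Bernoulli(q(T))`` that is conditionally independent of ``W`` given
``T``. The abandonment indicator is ``Δ = 1{T < W}``; the *observed*
announcement is ``Y = Y*·Δ`` (an announcement is only visible when the
subject abandons before service), and the recorded time is ``U = T`` for an
announced abandonment and ``U = W`` otherwise.

The study conditions emulated by default (both in hours):

* Setting 1 — T exponential with mean 16, W exponential with mean 2;
* Setting 2 — T Weibull with scale 16 and shape 1.5, W exponential mean 2;
* announcement probability q(t) = exp(-t) (decaying), with 1 - exp(-t) and
  the constant 1/2 as the documented alternatives.

The sub-stochastic densities of (U, category) are

    h1(t) = g(t) F̄(t),
    h2(t) = q(t) f(t) Ḡ(t),
    h3(t) = g(t) ∫₀ᵗ (1 - q(x)) f(x) dx,

with category probabilities p_i = ∫ h_i and conditional densities
r_i = h_i / p_i. These are evaluated here by adaptive quadrature and serve as
oracles for the estimators and their tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Tuple

import numpy as np
from scipy import integrate

from .data_model import SampleData
from .families import ParametricFamily

__all__ = [
    "AnnouncementFunction",
    "SimulationSetting",
    "simulate",
    "category_probabilities",
    "subdensities",
    "announced_subdistribution",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


@dataclass(frozen=True)
class AnnouncementFunction:
    """The announcement probability q(t) = P(Y=1 | T=t), mapping [0,∞)→[0,1].

    ``t`` is in the same unit as the simulation times (hours by default).
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        q = np.asarray(self.fn(t), dtype=float)
        if np.any((q < -1e-12) | (q > 1 + 1e-12)):
            raise ValueError(f"announcement function {self.name!r} left [0, 1]")
        return np.clip(q, 0.0, 1.0)

    @classmethod
    def exp_decay(cls) -> "AnnouncementFunction":
        return cls("exp_decay", lambda t: np.exp(-t))

    @classmethod
    def exp_rise(cls) -> "AnnouncementFunction":
        return cls("exp_rise", lambda t: 1.0 - np.exp(-t))

    @classmethod
    def constant(cls, c: float = 0.5) -> "AnnouncementFunction":
        if not 0.0 <= c <= 1.0:
            raise ValueError("constant announcement probability must be in [0, 1]")
        return cls(f"constant({c:g})", lambda t: np.full_like(np.asarray(t, dtype=float), c))

    @classmethod
    def custom(cls, fn: Callable, name: str = "custom") -> "AnnouncementFunction":
        return cls(name, fn)


@dataclass(frozen=True)
class SimulationSetting:
    """Families, announcement function, sample size, and seed for one run."""

    t_family: ParametricFamily
    w_family: ParametricFamily
    q: AnnouncementFunction
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def setting1(cls, n: int = 1000, seed: int = 0, q: AnnouncementFunction | None = None) -> "SimulationSetting":
        """Exponential failure times, mean 16 h; exponential waiting, mean 2 h."""
        return cls(
            ParametricFamily.exponential(mean=16.0),
            ParametricFamily.exponential(mean=2.0),
            q or AnnouncementFunction.exp_decay(),
            n=n,
            seed=seed,
        )

    @classmethod
    def setting2(cls, n: int = 1000, seed: int = 0, q: AnnouncementFunction | None = None) -> "SimulationSetting":
        """Weibull failure times (scale 16, shape 1.5); exponential waiting, mean 2 h."""
        return cls(
            ParametricFamily.weibull(scale=16.0, shape=1.5),
            ParametricFamily.exponential(mean=2.0),
            q or AnnouncementFunction.exp_decay(),
            n=n,
            seed=seed,
        )


def simulate(setting: SimulationSetting) -> SampleData:
    """Draw a sample of (U, Y, Δ) triplets; deterministic given the seed.

    The generator consumes randomness in a fixed order — T draws, then W
    draws, then the announcement uniforms — so runs are reproducible across
    calls with identical settings.
    """
    rng = np.random.default_rng(setting.seed)
    n = setting.n
    t = setting.t_family.rvs(n, rng)
    w = setting.w_family.rvs(n, rng)
    announce = rng.random(n) < setting.q(t)
    delta = (t < w).astype(np.int64)
    y = (announce & (delta == 1)).astype(np.int64)
    u = np.where(y == 1, t, w)
    return SampleData(u=u, y=y, delta=delta)


def subdensities(setting: SimulationSetting, t) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (h1, h2, h3) at times ``t`` (inner integral by quadrature)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    f, g, q = setting.t_family, setting.w_family, setting.q
    h1 = g.pdf(t) * f.survival(t)
    h2 = q(t) * f.pdf(t) * g.survival(t)
    silent = np.array(
        [integrate.quad(lambda x: (1.0 - q(x)) * f.pdf(x), 0.0, ti, **_QUAD_KW)[0] if ti > 0 else 0.0 for ti in t]
    )
    h3 = g.pdf(t) * silent
    return h1, h2, h3


def announced_subdistribution(setting: SimulationSetting, t) -> np.ndarray:
    """A(t) = ∫₀ᵗ q(s) f(s) ds, the announced-abandonment sub-distribution."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    f, q = setting.t_family, setting.q
    return np.array(
        [integrate.quad(lambda s: q(s) * f.pdf(s), 0.0, ti, **_QUAD_KW)[0] if ti > 0 else 0.0 for ti in t]
    )


def category_probabilities(setting: SimulationSetting) -> Tuple[float, float, float]:
    """(p1, p2, p3) by adaptive quadrature; must sum to 1 within 1e-6."""
    f, g, q = setting.t_family, setting.w_family, setting.q
    p1, e1 = integrate.quad(lambda w: g.pdf(w) * f.survival(w), 0.0, np.inf, **_QUAD_KW)
    p2, e2 = integrate.quad(lambda t: q(t) * f.pdf(t) * g.survival(t), 0.0, np.inf, **_QUAD_KW)

    def h3(w: float) -> float:
        inner, _ = integrate.quad(lambda x: (1.0 - q(x)) * f.pdf(x), 0.0, w, **_QUAD_KW)
        return g.pdf(w) * inner

    p3, e3 = integrate.quad(h3, 0.0, np.inf, **_QUAD_KW)
    total = p1 + p2 + p3
    if not math.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise RuntimeError(
            f"category probabilities failed to conserve mass: p1+p2+p3 = {total!r} "
            f"(quadrature error estimates {e1:.2e}, {e2:.2e}, {e3:.2e})"
        )
    return float(p1), float(p2), float(p3)
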