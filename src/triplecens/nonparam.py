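"""Nonparametric plug-in estimation of the failure-time distribution.

The identity underlying the estimator: writing p₁ = P(W ≤ T) (served),
p₃ = P(Y=0, T < W) (silent), r₁ and r₃ for the conditional densities of the
observed time within those categories, and A(t) = ∫₀ᵗ q(s) f(s) ds for the
announced-abandonment sub-distribution,

    F(t) = [p₃ r₃(t) + p₁ r₁(t) A(t)] / [p₃ r₃(t) + p₁ r₁(t)].

Each ingredient has a simple estimator:

* p̂₁, p̂₃ — empirical category frequencies;
* r̂₁, r̂₃ — Gaussian kernel density estimates with boundary reflection at 0
  and Silverman's bandwidth per category;
* Â(t) = 1 - exp(-D̂(t)) where D̂ is the jump sum Σ 1/(n·Ŷ(Uᵢ)) over announced
  abandonment times Uᵢ ≤ t, with risk set Ŷ(t) = n⁻¹Σ1{Uⱼ ≥ t} — the same
  algebra as one-minus-exp of a Nelson–Aalen cumulative-hazard estimator.

The raw plug-in estimate need not be monotone (it is a ratio of density
estimates); it is corrected by the cumulative sup (running maximum). Values
are not clipped to [0, 1] unless requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .data_model import SampleData

__all__ = [
    "NonparamFit",
    "estimate_probs",
    "estimate_A",
    "announced_jumps",
    "silverman_bandwidth",
    "estimate_r",
    "plugin_F",
    "monotonize",
    "fit_nonparam",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_DENOM_EPS = 1e-12


def estimate_probs(data: SampleData) -> Tuple[float, float]:
    """Empirical (P̂(W ≤ T), P̂(Y=0, T < W)) = (served, silent) frequencies."""
    if data.n == 0:
        raise ValueError("empty sample")
    p_right = float((1 - data.delta).mean())
    p_silent = float((data.delta * (1 - data.y)).mean())
    return p_right, p_silent


def announced_jumps(data: SampleData) -> Tuple[np.ndarray, np.ndarray]:
    """Jump times and increments of D̂: one term 1/(n·Ŷ(Uᵢ)) per announced event.

    The risk set is closed at t (``U ≥ t``), so the jumping observation is in
    its own risk set and the increment is always finite. Ties among announced
    times contribute separate jumps evaluated at the common risk-set size.
    """
    u2 = np.sort(data.u[(data.delta == 1) & (data.y == 1)])
    if u2.size == 0:
        return u2, u2
    u_sorted = np.sort(data.u)
    at_risk = data.n - np.searchsorted(u_sorted, u2, side="left")  # #{U >= t}, >= 1
    return u2, 1.0 / at_risk


def estimate_A(data: SampleData, grid) -> np.ndarray:
    """Â(t) = 1 - exp(-D̂(t)) evaluated on ``grid`` (right-continuous steps)."""
    grid = np.asarray(grid, dtype=float)
    times, jumps = announced_jumps(data)
    if times.size == 0:
        return np.zeros_like(grid)
    cum = np.concatenate([[0.0], np.cumsum(jumps)])
    d_hat = cum[np.searchsorted(times, grid, side="right")]
    return 1.0 - np.exp(-d_hat)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9·min(sd, IQR/1.34)·m^(-1/5)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("bandwidth selection needs at least 2 observations")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(np.mean(x))), 1.0) * 1e-3  # all-tied fallback
    return 0.9 * spread * x.size ** (-0.2)


def _kde_reflected(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    # Gaussian kernel, reflected at 0 so no mass leaks below the support.
    z = (grid[:, None] - x[None, :]) / bandwidth
    zr = (grid[:, None] + x[None, :]) / bandwidth
    k = np.exp(-0.5 * z**2) + np.exp(-0.5 * zr**2)
    return k.sum(axis=1) / (x.size * bandwidth * _SQRT2PI)


def estimate_r(
    data: SampleData,
    category: int,
    grid,
    bandwidth: Optional[float] = None,
) -> Tuple[np.ndarray, float]:
    """Kernel density estimate of the observed-time density within a category.

    Returns ``(values_on_grid, bandwidth_used)``. Only the served (1) and
    silent (3) categories are meaningful here.
    """
    if category not in (1, 3):
        raise ValueError("kernel estimation is defined for categories 1 and 3")
    grid = np.asarray(grid, dtype=float)
    x = data.u[data.categories == category]
    if x.size < 2:
        raise ValueError(f"too few observations in category {category} ({x.size}; need >= 2)")
    b = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x)
    if b <= 0:
        raise ValueError("bandwidth must be positive")
    return _kde_reflected(x, grid, b), b


def plugin_F(p_right, p_silent, r1, r3, A, grid=None) -> np.ndarray:
    """Combine the estimated components into the raw plug-in CDF estimate.

    Where both density terms fall below 1e-12 the ratio is degenerate (0/0);
    such points carry the last well-defined value forward (0 at the origin).
    """
    r1 = np.asarray(r1, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    A = np.asarray(A, dtype=float)
    num = p_silent * r3 + p_right * r1 * A
    den = p_silent * r3 + p_right * r1
    defined = den > _DENOM_EPS
    out = np.empty_like(den)
    last = 0.0
    for i in range(out.size):
        if defined[i]:
            last = num[i] / den[i]
        out[i] = last
    return out


def monotonize(F_raw) -> np.ndarray:
    """Cumulative-sup (running maximum) correction; idempotent."""
    return np.maximum.accumulate(np.asarray(F_raw, dtype=float))


@dataclass
class NonparamFit:
    """Plug-in fit on a grid over [0, τ]."""

    grid: np.ndarray
    tau: float
    p_right_hat: float
    p_silent_hat: float
    r1_hat: np.ndarray
    r3_hat: np.ndarray
    A_hat: np.ndarray
    F_raw: np.ndarray
    F_mono: np.ndarray
    bandwidths: Tuple[Optional[float], Optional[float]]
    counts: Tuple[int, int, int]

    def cdf(self, t) -> np.ndarray:
        """Monotonized estimate, linearly interpolated on the grid and held
        constant at F̂(τ) beyond τ."""
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.grid, self.F_mono, left=self.F_mono[0], right=self.F_mono[-1])

    def survival(self, t) -> np.ndarray:
        return 1.0 - self.cdf(t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.grid,
                "A_hat": self.A_hat,
                "r1_hat": self.r1_hat,
                "r3_hat": self.r3_hat,
                "F_raw": self.F_raw,
                "F_mono": self.F_mono,
            }
        )

    def summary(self) -> dict:
        return {
            "tau": self.tau,
            "bandwidth_r1": self.bandwidths[0],
            "bandwidth_r3": self.bandwidths[1],
            "n1": self.counts[0],
            "n2": self.counts[1],
            "n3": self.counts[2],
            "p_right_hat": self.p_right_hat,
            "p_silent_hat": self.p_silent_hat,
        }


def fit_nonparam(
    data: SampleData,
    tau: Optional[float] = None,
    tau_quantile: float = 0.95,
    n_grid: int = 512,
    bandwidths: Optional[Tuple[Optional[float], Optional[float]]] = None,
    clip: bool = False,
    min_n: int = 20,
) -> NonparamFit:
    """Orchestrate the plug-in estimator on an equally spaced grid over [0, τ].

    τ defaults to the ``tau_quantile`` empirical quantile of the observed
    times. A sample with no abandonment evidence at all (no announced and no
    silent observations) yields the degenerate estimate F̂ ≡ 0. A silent
    category with a single observation cannot support a kernel estimate; its
    density term is dropped (treated as zero) with a warning, as is a silent
    count below 10 (unstable r̂₃).
    """
    if data.n < min_n:
        raise ValueError(f"need at least {min_n} observations, got {data.n}")
    cats = data.categories
    n1, n2, n3 = int((cats == 1).sum()), int((cats == 2).sum()), int((cats == 3).sum())
    if n1 < 2:
        raise ValueError("served category too small for kernel estimation (need >= 2)")
    if tau is None:
        if not 0 < tau_quantile <= 1:
            raise ValueError("tau_quantile must be in (0, 1]")
        tau = float(np.quantile(data.u, tau_quantile))
    if tau <= 0:
        raise ValueError("tau must be positive")
    grid = np.linspace(0.0, tau, n_grid)

    p_right, p_silent = estimate_probs(data)
    b1 = b3 = None
    if bandwidths is not None:
        b1, b3 = bandwidths
    r1, b1 = estimate_r(data, 1, grid, bandwidth=b1)
    if n3 >= 2:
        if 0 < n3 < 10:
            warnings.warn(f"only {n3} silent observations; r3 estimate is unstable", UserWarning, stacklevel=2)
        r3, b3 = estimate_r(data, 3, grid, bandwidth=b3)
    else:
        if n3 == 1:
            warnings.warn("single silent observation dropped from the density term", UserWarning, stacklevel=2)
        r3 = np.zeros_like(grid)
        b3 = None
    A = estimate_A(data, grid)
    F_raw = plugin_F(p_right, p_silent, r1, r3, A, grid)
    if clip:
        F_raw = np.clip(F_raw, 0.0, 1.0)
    F_mono = monotonize(F_raw)
    return NonparamFit(
        grid=grid,
        tau=tau,
        p_right_hat=p_right,
        p_silent_hat=p_silent,
        r1_hat=r1,
        r3_hat=r3,
        A_hat=A,
        F_raw=F_raw,
        F_mono=F_mono,
        bandwidths=(b1, b3),
        counts=(n1, n2, n3),
    )
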