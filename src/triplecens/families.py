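"""Parametric failure/censoring-time families.

Thin, immutable wrappers around frozen :mod:`scipy.stats` distributions with
the parameterizations used throughout the package:

* exponential — parameterized by its *mean* in the user-facing constructors
  (the study settings quote means in hours) and by its *rate* internally;
* Weibull — parameterized by scale ``λ`` and shape ``k``, with survival
  ``exp(-(t/λ)^k)``.

A family carries both its frozen distribution (for pdf/survival/quantile
evaluation and random draws) and a packed positive parameter vector, so the
likelihood optimizers can rebuild a family from a candidate vector via
:meth:`ParametricFamily.with_vector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = ["ParametricFamily"]

_SUPPORTED = ("exponential", "weibull")


@dataclass(frozen=True)
class ParametricFamily:
    """A named nonnegative failure-time family.

    Parameters
    ----------
    name:
        ``"exponential"`` or ``"weibull"``.
    params:
        Packed positive parameter vector: ``(rate,)`` for the exponential,
        ``(scale, shape)`` for the Weibull.
    """

    name: str
    params: Tuple[float, ...]
    _dist: object = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.name not in _SUPPORTED:
            raise ValueError(f"unsupported family {self.name!r}; expected one of {_SUPPORTED}")
        params = tuple(float(p) for p in self.params)
        if any(not np.isfinite(p) or p <= 0 for p in params):
            raise ValueError(f"{self.name} parameters must be positive and finite, got {params}")
        object.__setattr__(self, "params", params)
        if self.name == "exponential":
            if len(params) != 1:
                raise ValueError("exponential family takes a single rate parameter")
            dist = stats.expon(scale=1.0 / params[0])
        else:
            if len(params) != 2:
                raise ValueError("weibull family takes (scale, shape)")
            scale, shape = params
            dist = stats.weibull_min(shape, scale=scale)
        object.__setattr__(self, "_dist", dist)

    # ---- constructors -------------------------------------------------

    @classmethod
    def exponential(cls, *, mean: float | None = None, rate: float | None = None) -> "ParametricFamily":
        """Exponential family from either its mean or its rate (exactly one)."""
        if (mean is None) == (rate is None):
            raise ValueError("give exactly one of mean= or rate=")
        return cls("exponential", (1.0 / mean if mean is not None else rate,))

    @classmethod
    def weibull(cls, *, scale: float, shape: float) -> "ParametricFamily":
        return cls("weibull", (scale, shape))

    def with_vector(self, vector) -> "ParametricFamily":
        """Same family shape with a new packed parameter vector."""
        return ParametricFamily(self.name, tuple(np.asarray(vector, dtype=float)))

    # ---- evaluation ----------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def mean(self) -> float:
        return float(self._dist.mean())

    def pdf(self, t):
        return self._dist.pdf(t)

    def logpdf(self, t):
        return self._dist.logpdf(t)

    def cdf(self, t):
        return self._dist.cdf(t)

    def survival(self, t):
        return self._dist.sf(t)

    def log_survival(self, t):
        return self._dist.logsf(t)

    def quantile(self, p):
        return self._dist.ppf(p)

    def rvs(self, size: int, rng: np.random.Generator):
        return self._dist.rvs(size=size, random_state=rng)

    def describe(self) -> dict:
        if self.name == "exponential":
            return {"family": "exponential", "rate": self.params[0], "mean": self.mean}
        return {"family": "weibull", "scale": self.params[0], "shape": self.params[1]}
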