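"""Core observation types, category logic, and delimited-text I/O.

A subject is recorded as a triplet ``(u, y, delta)``:

* ``u`` — observed time (nonnegative, hours by default),
* ``delta`` — abandonment indicator, 1 if the subject lost patience before
  service would have been offered,
* ``y`` — announcement indicator, 1 if the abandonment was announced.

The triplet determines one of three categories:

===========  =====  =======  ==========================================
category     delta  y        meaning
===========  =====  =======  ==========================================
1 (served)   0      0        service received; failure time right-censored
2 (announced) 1     1        announced abandonment; failure time observed
3 (silent)   1      0        silent abandonment; failure time left-censored
===========  =====  =======  ==========================================

``(delta=0, y=1)`` is unobservable — the recorded time is ``U = YT + (1-Y)W``
and an announcement is only seen when the subject actually abandons — and is
rejected as invalid.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "Observation",
    "SampleData",
    "CategoryCounts",
    "InvalidObservationError",
    "categorize",
    "category_counts",
    "read_sample",
    "write_sample",
    "convert_time_unit",
]

TIME_UNITS = ("hours", "minutes")
DEFAULT_COLUMNS: Mapping[str, str] = {"u": "u", "y": "y", "delta": "delta", "stratum": "stratum"}


class InvalidObservationError(ValueError):
    """Raised for observations violating the (u, y, delta) invariants."""


class Category(enum.IntEnum):
    SERVED = 1
    ANNOUNCED = 2
    SILENT = 3


@dataclass(frozen=True)
class Observation:
    """One subject's triplet (observed time, announcement, abandonment)."""

    u: float
    y: int
    delta: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.u) or self.u < 0:
            raise InvalidObservationError(f"observed time must be finite and >= 0, got u={self.u}")
        if self.y not in (0, 1) or self.delta not in (0, 1):
            raise InvalidObservationError(f"y and delta must be 0/1, got y={self.y}, delta={self.delta}")
        if self.y == 1 and self.delta == 0:
            raise InvalidObservationError(
                "y=1 with delta=0 is unobservable: an announcement is only seen when the subject abandons"
            )


def categorize(obs: Observation) -> Category:
    """Map a valid observation to its category (see module truth table)."""
    if obs.delta == 0:
        return Category.SERVED
    return Category.ANNOUNCED if obs.y == 1 else Category.SILENT


@dataclass
class SampleData:
    """An ordered sample of (u, y, delta) triplets.

    ``time_unit`` is metadata only; all computations are unit-agnostic.
    Zero observed times are legal but flagged with a warning, since case-study
    practice excludes subjects served (or abandoning) upon arrival — that
    exclusion is left to the caller.
    """

    u: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    stratum: Optional[str] = None
    time_unit: str = "hours"

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.delta = np.asarray(self.delta, dtype=np.int64)
        if self.u.ndim != 1 or self.u.size == 0:
            raise ValueError("sample must be a nonempty 1-d collection")
        if not (self.u.shape == self.y.shape == self.delta.shape):
            raise ValueError("u, y, delta must have identical shapes")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {TIME_UNITS}")
        bad = ~np.isfinite(self.u) | (self.u < 0)
        bad |= ~np.isin(self.y, (0, 1)) | ~np.isin(self.delta, (0, 1))
        bad |= (self.y == 1) & (self.delta == 0)
        if bad.any():
            rows = np.flatnonzero(bad)
            raise InvalidObservationError(
                f"invalid observations at rows {rows.tolist()[:20]}"
                + (" ..." if rows.size > 20 else "")
            )
        if (self.u == 0).any():
            warnings.warn(
                "sample contains zero observed times (subjects served or abandoning "
                "upon arrival); consider excluding them before estimation",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return int(self.u.size)

    @property
    def categories(self) -> np.ndarray:
        """Per-observation category values in {1, 2, 3}."""
        return np.where(self.delta == 0, 1, np.where(self.y == 1, 2, 3))

    def subset(self, mask: np.ndarray) -> "SampleData":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return SampleData(self.u[mask], self.y[mask], self.delta[mask], self.stratum, self.time_unit)

    def resample(self, rng: np.random.Generator) -> "SampleData":
        """Nonparametric bootstrap resample of triplets, with replacement."""
        idx = rng.integers(0, self.n, size=self.n)
        return self.subset(idx)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"u": self.u, "y": self.y, "delta": self.delta})
        if self.stratum is not None:
            df["stratum"] = self.stratum
        return df


@dataclass(frozen=True)
class CategoryCounts:
    """Counts (n1, n2, n3) of served / announced / silent observations."""

    n1: int
    n2: int
    n3: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def proportions(self) -> tuple:
        n = self.n
        if n == 0:
            raise ValueError("empty sample")
        return (self.n1 / n, self.n2 / n, self.n3 / n)

    def percentages(self, decimals: int = 1) -> tuple:
        """Proportions as percentages, rounded for display only."""
        return tuple(round(100.0 * p, decimals) for p in self.proportions)


def category_counts(data: SampleData) -> CategoryCounts:
    """Category accounting of a sample; proportions sum to 1 before rounding."""
    cats = data.categories
    return CategoryCounts(int((cats == 1).sum()), int((cats == 2).sum()), int((cats == 3).sum()))


def convert_time_unit(data: SampleData, to: str) -> SampleData:
    """Convert observed times between hours and minutes (metadata-aware)."""
    if to not in TIME_UNITS:
        raise ValueError(f"time unit must be one of {TIME_UNITS}")
    if to == data.time_unit:
        return data
    factor = 60.0 if to == "minutes" else 1.0 / 60.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return SampleData(data.u * factor, data.y, data.delta, data.stratum, to)


def _resolve_columns(columns: Optional[Mapping[str, str]]) -> Dict[str, str]:
    out = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown column roles {sorted(unknown)}")
        out.update(columns)
    return out


def read_sample(
    path,
    columns: Optional[Mapping[str, str]] = None,
    time_unit: str = "hours",
) -> Union[SampleData, Dict[str, SampleData]]:
    """Read a sample from a header-ed CSV file.

    The canonical schema is ``u,y,delta[,stratum]``; ``columns`` remaps role
    names to file column names. Returns a single :class:`SampleData` when no
    stratum column is present, otherwise a dict keyed by stratum label.
    Rows violating the observation invariants raise
    :class:`InvalidObservationError` naming the offending data rows (1-based,
    excluding the header).
    """
    cols = _resolve_columns(columns)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty file: {path}")
    for role in ("u", "y", "delta"):
        if cols[role] not in df.columns:
            raise ValueError(f"missing column {cols[role]!r} (role {role}) in {path}")
    u = pd.to_numeric(df[cols["u"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    delta = pd.to_numeric(df[cols["delta"]], errors="coerce")
    bad = (
        u.isna() | y.isna() | delta.isna()
        | ~np.isfinite(u.fillna(np.nan))
        | (u < 0)
        | ~y.isin([0, 1])
        | ~delta.isin([0, 1])
        | ((y == 1) & (delta == 0))
    )
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise InvalidObservationError(
            f"invalid rows in {path}: data rows {rows[:20]}" + (" ..." if len(rows) > 20 else "")
        )
    strat_col = cols["stratum"]
    if strat_col in df.columns:
        out: Dict[str, SampleData] = {}
        for label, grp in df.groupby(strat_col, sort=True):
            out[str(label)] = SampleData(
                u[grp.index].to_numpy(),
                y[grp.index].to_numpy(dtype=np.int64),
                delta[grp.index].to_numpy(dtype=np.int64),
                stratum=str(label),
                time_unit=time_unit,
            )
        return out
    return SampleData(u.to_numpy(), y.to_numpy(dtype=np.int64), delta.to_numpy(dtype=np.int64), time_unit=time_unit)


def write_sample(data: SampleData, path, float_format: str = "%.12g") -> None:
    """Write a sample as canonical CSV (round-trips through read_sample)."""
    data.to_dataframe().to_csv(path, index=False, float_format=float_format)
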