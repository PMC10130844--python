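"""Natural cubic spline exposure basis and integer-lag cross-basis.

The exposure–response is a natural cubic spline in Tmin (default 3 df:
two interior knots at the 33.3/66.7 percentiles of the analysis-sample
warm-season distribution, boundary knots at the observed min/max).  The
lag structure is an unconstrained integer-lag basis over lags 0–5: one
full copy of the spline basis per lag day, so the cross-basis has
``df × (lag_max − lag_min + 1)`` columns, ordered lag-major.

The spline basis uses the truncated-power natural-spline construction
(ESL-style): with knots ξ₁ < … < ξ_K (boundary knots included, K = df+1),
the no-intercept basis is

    N₁(x) = x,   N_{k+1}(x) = d_k(x) − d_{K−1}(x),  k = 1..K−2,
    d_k(x) = [(x − ξ_k)₊³ − (x − ξ_K)₊³] / (ξ_K − ξ_k).

This is C² everywhere, cubic between knots and linear beyond the
boundary knots.  Any invertible column transform of this basis spans the
same space and yields identical fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import CityTemperatureSeries, GapError

__all__ = ["SplineSpec", "CrossBasisSpec", "ns_basis", "build_crossbasis"]


@dataclass
class SplineSpec:
    """Parameterization of the natural cubic spline exposure basis.

    ``df = 1 + len(interior_knots)`` for the no-intercept natural basis.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        self.interior_knots = tuple(float(k) for k in self.interior_knots)
        self.boundary_knots = (
            float(self.boundary_knots[0]),
            float(self.boundary_knots[1]),
        )
        knots = self.all_knots
        if any(b >= a for b, a in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")

    @property
    def df(self) -> int:
        return 1 + len(self.interior_knots)

    @property
    def all_knots(self) -> tuple[float, ...]:
        return (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])

    @classmethod
    def from_data(cls, x, df: int = 3) -> "SplineSpec":
        """Place df−1 interior knots at equally spaced quantiles of ``x``.

        For the default df = 3 the interior knots sit at the 33.3rd and
        66.7th percentiles; boundary knots at the observed min/max.
        """
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        qs = np.arange(1, df) / df
        interior = tuple(np.quantile(x, qs, method="linear")) if df > 1 else ()
        return cls(interior_knots=interior, boundary_knots=(float(x.min()), float(x.max())))

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
        }


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis (no intercept column).

    Returns an array of shape ``(len(x), spec.df)``.  Deterministic in
    (x, spec); repeated x values produce identical rows.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("spline basis input must be finite")
    knots = np.asarray(spec.all_knots)
    K = len(knots)
    cols = [x]
    if K > 2:
        xK, xKm1 = knots[-1], knots[-2]

        def d(k: int) -> np.ndarray:
            return (
                np.clip(x - knots[k], 0.0, None) ** 3
                - np.clip(x - xK, 0.0, None) ** 3
            ) / (xK - knots[k])

        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class CrossBasisSpec:
    """Spline-in-exposure × integer-lag cross-basis parameterization."""

    spline: SplineSpec
    lag_min: int = 0
    lag_max: int = 5

    def __post_init__(self) -> None:
        if self.lag_min > self.lag_max or self.lag_min < 0:
            raise ValueError("need 0 <= lag_min <= lag_max")

    @property
    def n_lags(self) -> int:
        return self.lag_max - self.lag_min + 1

    @property
    def n_columns(self) -> int:
        return self.spline.df * self.n_lags

    def column_names(self) -> list[str]:
        return [
            f"lag{l}_ns{j + 1}"
            for l in range(self.lag_min, self.lag_max + 1)
            for j in range(self.spline.df)
        ]

    def to_dict(self) -> dict:
        return {
            "spline": self.spline.to_dict(),
            "lag_min": self.lag_min,
            "lag_max": self.lag_max,
            "column_order": "lag-major, spline-column-minor",
        }


def build_crossbasis(
    exposure: CityTemperatureSeries, dates, spec: CrossBasisSpec
) -> np.ndarray:
    """Cross-basis rows for the given dates.

    Row for date d, lag block l (lag-major order) is the spline basis
    evaluated at Tmin on day d − l.  Raises :class:`GapError` naming the
    first uncovered (date, lag) pair.
    """
    idx = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(dates))).normalize()
    blocks = []
    for lag in range(spec.lag_min, spec.lag_max + 1):
        shifted = idx - pd.Timedelta(days=lag)
        vals = exposure.frame["tmin_f"].reindex(shifted)
        if vals.isna().to_numpy().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise GapError(
                f"exposure gap for date {idx[i].date()} at lag {lag} "
                f"(needs {shifted[i].date()})"
            )
        blocks.append(ns_basis(vals.to_numpy(), spec.spline))
    return np.hstack(blocks)
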