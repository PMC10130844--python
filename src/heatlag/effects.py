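"""Cumulative exposure–response curves, minimum-risk temperature, ORs, and
subgroup heterogeneity.

With an integer-lag cross-basis, the cumulative (lag 0–5) log odds ratio
for temperature t versus a reference r places the same spline difference
b(t) − b(r) in every lag block:

    c(t) = [b(t) − b(r), …, b(t) − b(r)]   (one copy per lag)
    cum log-OR(t) = c(t)·β̂,  SE(t) = sqrt(c(t)ᵀ Σ̂ c(t)).

The minimum-risk temperature (MRT) is the grid temperature at which the
fitted cumulative curve is lowest over the observed warm-season range;
the curve is then re-referenced at the MRT, so the reported OR compares
an elevated temperature (default the warm-season 95th percentile) to the
temperature with the fewest encounters.  Confidence intervals are Wald
intervals on the log scale; uncertainty in the MRT location itself is not
propagated (the conventional practice in this literature — see the
methods note for the caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clogit import FitResult
from .dlnm import CrossBasisSpec, ns_basis

__all__ = [
    "ExposureResponseCurve",
    "SubgroupEstimate",
    "exposure_response_curve",
    "find_mrt",
    "mrt_referenced_curve",
    "cumulative_or",
    "cochran_q",
]


@dataclass
class ExposureResponseCurve:
    """Cumulative log-OR and SE over a temperature grid, with reference."""

    grid: np.ndarray
    cum_log_or: np.ndarray
    se: np.ndarray
    reference: float
    mrt: float | None = None
    metadata: dict = field(default_factory=dict)

    def at(self, t: float) -> tuple[float, float]:
        """Linearly interpolated (cum log-OR, SE) at temperature ``t``."""
        if not (self.grid[0] - 1e-9 <= t <= self.grid[-1] + 1e-9):
            raise ValueError(
                f"{t}°F outside curve grid [{self.grid[0]}, {self.grid[-1]}]"
            )
        return (
            float(np.interp(t, self.grid, self.cum_log_or)),
            float(np.interp(t, self.grid, self.se)),
        )


@dataclass
class SubgroupEstimate:
    """A subgroup's cumulative OR at elevated temperature vs its MRT."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    n_encounters: int
    log_or: float = 0.0
    se: float = 0.0
    mrt: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("need 0 < ci_low <= OR <= ci_high")


def _contrast(grid, reference, fit: FitResult, spec: CrossBasisSpec) -> np.ndarray:
    b = ns_basis(np.asarray(grid, dtype=float), spec.spline)
    b_ref = ns_basis([float(reference)], spec.spline)
    diff = b - b_ref
    C = np.tile(diff, (1, spec.n_lags))
    extra = fit.beta.shape[0] - C.shape[1]
    if extra < 0:
        raise ValueError("fit has fewer coefficients than the cross-basis")
    if extra:
        # appended covariates (e.g. RH adjustment) do not enter the contrast
        C = np.hstack([C, np.zeros((C.shape[0], extra))])
    return C


def exposure_response_curve(
    fit: FitResult,
    spec: CrossBasisSpec,
    grid,
    reference: float,
) -> ExposureResponseCurve:
    """Cumulative lag-0–5 log-OR curve over ``grid``, referenced at ``reference``.

    Requires a converged fit.  Grid points beyond the spline's boundary
    knots are in the linear extrapolation region; a warning is emitted.
    """
    if not fit.converged:
        raise ValueError("exposure_response_curve requires a converged fit")
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.spline.boundary_knots
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        warnings.warn(
            "curve grid extends beyond the spline boundary knots; "
            "values there are linear extrapolations",
            stacklevel=2,
        )
    C = _contrast(grid, reference, fit, spec)
    cum = C @ fit.beta
    var = np.einsum("ij,jk,ik->i", C, fit.cov, C)
    se = np.sqrt(np.clip(var, 0.0, None))
    return ExposureResponseCurve(
        grid=grid,
        cum_log_or=cum,
        se=se,
        reference=float(reference),
        metadata=spec.to_dict(),
    )


def find_mrt(curve: ExposureResponseCurve) -> float:
    """Grid temperature minimizing the cumulative curve (ties → lowest °F).

    The minimizer is invariant to the curve's reference: re-referencing
    shifts the whole curve by a constant.
    """
    if curve.grid.size == 0:
        raise ValueError("empty curve grid")
    return float(curve.grid[int(np.argmin(curve.cum_log_or))])


def mrt_referenced_curve(
    fit: FitResult,
    spec: CrossBasisSpec,
    t_lo: float,
    t_hi: float,
    step: float = 0.1,
) -> ExposureResponseCurve:
    """Two-pass MRT-referenced curve over the observed exposure range.

    Pass 1 evaluates the curve on a grid from ``t_lo`` to ``t_hi`` at
    ``step`` °F resolution against a provisional reference and locates
    its minimum (the MRT); pass 2 recomputes all contrasts against the
    MRT so the reported curve is zero, with zero SE, exactly there.
    """
    # linspace keeps the grid inside [t_lo, t_hi] at resolution <= step
    n = max(int(np.ceil((t_hi - t_lo) / step)), 1)
    grid = np.linspace(t_lo, t_hi, n + 1)
    provisional = exposure_response_curve(fit, spec, grid, reference=grid[0])
    mrt = find_mrt(provisional)
    curve = exposure_response_curve(fit, spec, grid, reference=mrt)
    curve.mrt = mrt
    return curve


def cumulative_or(
    curve: ExposureResponseCurve, t: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Cumulative OR at ``t`` vs the curve's reference, with a Wald CI."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    log_or, se = curve.at(t)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
    )


def cochran_q(estimates: list[tuple[float, float]]) -> tuple[float, int, float]:
    """Cochran's Q homogeneity test over subgroup (log-OR, SE) pairs.

    Fixed-effect weights w = 1/SE²; Q = Σ w (θ − θ̄)² with the
    inverse-variance pooled mean θ̄, referred to χ²(k−1).
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least two estimates")
    theta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p
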