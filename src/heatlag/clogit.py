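"""Conditional logistic regression for 1:m matched sets.

The conditional likelihood conditions on one event per matched set: for
stratum i with case row x_case and referent rows x_j,

    ℓ(β) = Σ_i [ x_case,i·β − log Σ_{j ∈ case ∪ referents} exp(x_j,i·β) ].

Any covariate constant within a stratum drops out — the mathematical
content of "cases serve as their own controls".  The fitter maximizes
this likelihood directly by Newton–Raphson with analytic gradient and
Hessian and step-halving; m ≤ 4 referents makes the exact sum cheap, so
no proportional-hazards reformulation is used.

Numerical choices (package defaults, not taken from any source data):
start at β = 0, converge when max |score| < 1e-8 or the relative
log-likelihood change < 1e-12, at most 50 iterations.  The covariance is
the inverse observed information at the optimum.  Separation and other
non-identifiability are reported, never silently shrunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import Stratum

__all__ = [
    "FitResult",
    "FitError",
    "conditional_loglik",
    "fit_conditional_logistic",
]


class FitError(RuntimeError):
    """The conditional likelihood could not be maximized."""


@dataclass
class FitResult:
    """A converged (or diagnosed) conditional-logistic fit."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_strata: int
    n_informative_strata: int
    converged: bool
    iterations: int
    metadata: dict = field(default_factory=dict)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_json(self, path) -> None:
        doc = {
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "n_informative_strata": self.n_informative_strata,
            "converged": self.converged,
            "iterations": self.iterations,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _stack(strata: list[Stratum]):
    """Stack stratum rows; case row first within each block."""
    sizes = np.array([s.rows.shape[0] for s in strata])
    X = np.vstack([s.rows for s in strata])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    seg = np.repeat(np.arange(len(strata)), sizes)
    return X, starts, seg


def _loglik_parts(beta, X, starts, seg, need_derivs=True):
    eta = X @ beta
    # per-stratum max for a numerically stable log-sum-exp
    mx = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - mx[seg])
    denom = np.add.reduceat(z, starts)
    ll = float(np.sum(eta[starts] - (mx + np.log(denom))))
    if not need_derivs:
        return ll, None, None
    p = z / denom[seg]
    M = np.add.reduceat(X * p[:, None], starts, axis=0)  # per-stratum mean row
    grad = X[starts].sum(axis=0) - M.sum(axis=0)
    info = (X * p[:, None]).T @ X - M.T @ M  # observed information
    return ll, grad, info


def conditional_loglik(beta, strata: list[Stratum]) -> float:
    """Conditional log-likelihood of ``beta`` over the matched sets."""
    beta = np.asarray(beta, dtype=float)
    if not strata:
        raise FitError("no strata")
    if beta.shape[0] != strata[0].rows.shape[1]:
        raise ValueError(
            f"beta has {beta.shape[0]} entries but design rows have "
            f"{strata[0].rows.shape[1]} columns"
        )
    X, starts, seg = _stack(strata)
    ll, _, _ = _loglik_parts(beta, X, starts, seg, need_derivs=False)
    return ll


def _separating_columns(strata: list[Stratum]) -> list[int]:
    """Columns whose case value weakly dominates (or is dominated by) every
    referent in every informative stratum — the classic separation pattern."""
    p = strata[0].rows.shape[1]
    above = np.ones(p, dtype=bool)
    below = np.ones(p, dtype=bool)
    strict = np.zeros(p, dtype=bool)
    for s in strata:
        if not s.informative:
            continue
        case, refs = s.rows[0], s.rows[1:]
        above &= (case >= refs.max(axis=0) - 1e-12)
        below &= (case <= refs.min(axis=0) + 1e-12)
        strict |= (case > refs.max(axis=0) + 1e-12) | (case < refs.min(axis=0) - 1e-12)
    return [int(j) for j in np.flatnonzero((above | below) & strict)]


def fit_conditional_logistic(
    strata: list[Stratum],
    *,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_reltol: float = 1e-12,
) -> FitResult:
    """Maximize the conditional likelihood by damped Newton–Raphson.

    Uninformative strata (all rows identical) contribute only a constant
    to the likelihood; they are counted in ``n_strata`` but carry no
    information.  Raises :class:`FitError` on zero informative strata or
    a non-identifiable design (singular information / separation), naming
    the offending columns where detectable.
    """
    if not strata:
        raise FitError("no strata")
    informative = [s for s in strata if s.informative]
    if not informative:
        raise FitError("zero informative strata: exposure constant within every stratum")
    sep = _separating_columns(informative)
    if sep:
        raise FitError(
            f"separation: columns {sep} perfectly rank cases against referents; "
            "the conditional MLE is infinite"
        )
    X, starts, seg = _stack(informative)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _loglik_parts(beta, X, starts, seg)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            sep = _separating_columns(informative)
            raise FitError(
                "singular information matrix (non-identifiable design)"
                + (f"; separation suspected in columns {sep}" if sep else "")
            )
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _loglik_parts(cand, X, starts, seg)
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        else:
            raise FitError("step-halving failed to improve the likelihood")
        rel_change = abs(ll_new - ll) / max(1.0, abs(ll))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if rel_change < loglik_reltol:
            converged = True
            break
    if np.max(np.abs(grad)) < score_tol:
        converged = True
    if not converged or not np.isfinite(beta).all():
        sep = _separating_columns(informative)
        if sep:
            raise FitError(f"separation: columns {sep} perfectly rank cases vs referents")
        raise FitError(f"no convergence in {max_iter} iterations (max|score|={np.max(np.abs(grad)):.2e})")
    eigvals = np.linalg.eigvalsh(info)
    if eigvals.min() <= 1e-10 * max(1.0, eigvals.max()):
        sep = _separating_columns(informative)
        raise FitError(
            "observed information not positive definite at the optimum"
            + (f"; separation suspected in columns {sep}" if sep else "")
        )
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    # add back the constant contribution of uninformative strata
    ll_total = ll + sum(
        -np.log(s.rows.shape[0]) for s in strata if not s.informative
    )
    return FitResult(
        beta=beta,
        cov=cov,
        loglik=float(ll_total),
        n_strata=len(strata),
        n_informative_strata=len(informative),
        converged=converged,
        iterations=n_iter,
    )
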