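"""Independent oracles used by the tests.

Everything here is deliberately naive — plain-Python loops and
brute-force optimization — and shares no code path with the package's
vectorized implementations.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
from scipy import optimize

from heatlag.design import Stratum

_DUMMY_DATE = dt.date(2005, 6, 15)


def make_stratum(case_row, referent_rows, labels=None) -> Stratum:
    """Build a stratum from raw design rows (case first)."""
    rows = np.vstack([np.atleast_1d(case_row)]
                     + [np.atleast_1d(r) for r in referent_rows]).astype(float)
    refs = tuple(_DUMMY_DATE + dt.timedelta(days=7 * (i + 1))
                 for i in range(len(referent_rows)))
    informative = bool(np.ptp(rows, axis=0).max() > 0)
    return Stratum(
        case_date=_DUMMY_DATE,
        referent_dates=refs,
        labels=labels or {},
        rows=rows,
        informative=informative,
    )


def naive_conditional_loglik(beta, strata) -> float:
    """Textbook conditional log-likelihood, one stratum at a time."""
    from scipy.special import logsumexp

    total = 0.0
    for s in strata:
        etas = [float(np.dot(row, beta)) for row in s.rows]
        total += etas[0] - logsumexp(etas)
    return total


def brute_force_fit(strata, n_params, half_width=4.0) -> np.ndarray:
    """Maximize the naive conditional likelihood by coarse grid search
    followed by golden-section (1-d) or Nelder–Mead polish."""

    def neg(beta):
        return -naive_conditional_loglik(np.asarray(beta, dtype=float), strata)

    if n_params == 1:
        res = optimize.minimize_scalar(
            lambda b: neg([b]), bounds=(-half_width, half_width), method="bounded",
            options={"xatol": 1e-10},
        )
        return np.array([res.x])
    grid = np.linspace(-half_width, half_width, 9)
    best, best_val = None, np.inf
    mesh = np.meshgrid(*([grid] * n_params))
    for point in np.stack([m.ravel() for m in mesh], axis=1):
        v = neg(point)
        if v < best_val:
            best, best_val = point, v
    res = optimize.minimize(neg, best, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return np.asarray(res.x)


def random_small_fixture(rng, max_strata=10, n_params=2):
    """A random identifiable matched-set fixture (≤ max_strata strata)."""
    while True:
        n_strata = int(rng.integers(min(4, max_strata), max_strata + 1))
        strata = []
        for _ in range(n_strata):
            m = int(rng.integers(1, 5))  # 1-4 referents
            rows = rng.normal(0.0, 1.0, size=(m + 1, n_params))
            strata.append(make_stratum(rows[0], rows[1:]))
        # accept only clearly identifiable fixtures with an interior
        # optimum (quasi-separated draws push the MLE toward infinity)
        X = np.vstack([s.rows - s.rows.mean(axis=0) for s in strata])
        if np.linalg.matrix_rank(X) < n_params or min(
            np.linalg.svd(X, compute_uv=False)
        ) <= 0.5:
            continue
        res = optimize.minimize(
            lambda b: -naive_conditional_loglik(b, strata),
            np.zeros(n_params), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if np.abs(res.x).max() < 2.5:
            return strata
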