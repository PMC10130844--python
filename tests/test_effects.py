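import math

import numpy as np
import pytest
from scipy import stats

import heatlag as hl
from heatlag.clogit import FitResult
from heatlag.dlnm import CrossBasisSpec, SplineSpec, ns_basis
from heatlag.effects import (
    ExposureResponseCurve,
    cochran_q,
    cumulative_or,
    exposure_response_curve,
    find_mrt,
)


def _toy_fit(beta, cov, n=10):
    beta = np.asarray(beta, dtype=float)
    return FitResult(
        beta=beta, cov=np.asarray(cov, dtype=float), loglik=-1.0,
        n_strata=n, n_informative_strata=n, converged=True, iterations=3,
    )


def _spec_df1():
    # df=1 spline: basis is x itself, so the hand algebra is explicit
    return CrossBasisSpec(
        spline=SplineSpec(interior_knots=(), boundary_knots=(0.0, 10.0)),
        lag_min=0, lag_max=1,
    )


class TestExposureResponseCurve:
    def test_hand_linear_algebra_oracle(self):
        # 2 columns (1 spline col x 2 lags), explicit beta and cov:
        # contrast at t vs ref is [t-ref, t-ref]
        beta = [0.03, 0.01]
        cov = [[0.0004, 0.0001], [0.0001, 0.0009]]
        curve = exposure_response_curve(_toy_fit(beta, cov), _spec_df1(),
                                        grid=[2.0, 5.0, 8.0], reference=5.0)
        for i, t in enumerate([2.0, 5.0, 8.0]):
            c = np.array([t - 5.0, t - 5.0])
            assert curve.cum_log_or[i] == pytest.approx(c @ np.array(beta))
            assert curve.se[i] == pytest.approx(
                math.sqrt(c @ np.array(cov) @ c)
            )

    def test_reference_point_is_exact_zero(self):
        curve = exposure_response_curve(_toy_fit([0.1, 0.2], np.eye(2) * 0.01),
                                        _spec_df1(), grid=[3.0, 5.0], reference=5.0)
        assert curve.cum_log_or[1] == 0.0
        assert curve.se[1] == 0.0

    def test_zero_beta_gives_flat_curve(self):
        curve = exposure_response_curve(_toy_fit([0.0, 0.0], np.eye(2) * 0.01),
                                        _spec_df1(), grid=[1.0, 4.0, 9.0],
                                        reference=4.0)
        np.testing.assert_array_equal(curve.cum_log_or, 0.0)
        assert curve.se[0] > 0 and curve.se[2] > 0

    def test_unconverged_fit_rejected(self):
        bad = _toy_fit([0.1, 0.1], np.eye(2))
        bad.converged = False
        with pytest.raises(ValueError):
            exposure_response_curve(bad, _spec_df1(), [1.0], 1.0)

    def test_rereferencing_shifts_by_constant_and_or_inverts(self):
        fit = _toy_fit([0.05, -0.02], [[0.001, 0.0002], [0.0002, 0.002]])
        spec = _spec_df1()
        grid = np.linspace(0.0, 10.0, 21)
        c1 = exposure_response_curve(fit, spec, grid, reference=2.0)
        c2 = exposure_response_curve(fit, spec, grid, reference=8.0)
        diff = c1.cum_log_or - c2.cum_log_or
        np.testing.assert_allclose(diff, diff[0], atol=1e-12)
        # OR(t vs r) * OR(r vs t) = 1
        or_t, _, _ = cumulative_or(c1, 8.0)
        or_r, _, _ = cumulative_or(c2, 2.0)
        assert or_t * or_r == pytest.approx(1.0, rel=1e-12)


class TestFindMrt:
    def test_flat_curve_tie_breaks_to_lowest_temperature(self):
        curve = ExposureResponseCurve(
            grid=np.array([60.0, 65.0, 70.0]),
            cum_log_or=np.zeros(3), se=np.zeros(3), reference=60.0,
        )
        assert find_mrt(curve) == 60.0

    def test_strictly_increasing_curve_gives_range_minimum(self):
        curve = ExposureResponseCurve(
            grid=np.array([60.0, 65.0, 70.0]),
            cum_log_or=np.array([0.0, 0.1, 0.3]), se=np.zeros(3), reference=60.0,
        )
        assert find_mrt(curve) == 60.0

    def test_parabolic_curve_recovers_vertex(self):
        # a cumulative response that is a parabola with vertex 69.2:
        # the grid minimizer must land within one grid step of the vertex
        grid = np.arange(50.0, 83.05, 0.1)
        curve = ExposureResponseCurve(
            grid=grid,
            cum_log_or=0.024 * (grid - 69.2) ** 2,
            se=np.full_like(grid, 0.01),
            reference=grid[0],
        )
        assert find_mrt(curve) == pytest.approx(69.2, abs=0.1 + 1e-9)

    def test_empty_grid_rejected(self):
        curve = ExposureResponseCurve(
            grid=np.array([]), cum_log_or=np.array([]), se=np.array([]),
            reference=0.0,
        )
        with pytest.raises(ValueError):
            find_mrt(curve)


class TestCumulativeOr:
    def test_reference_point_unit_or(self):
        curve = exposure_response_curve(
            _toy_fit([0.1, 0.2], np.eye(2) * 0.01), _spec_df1(),
            grid=[3.0, 5.0], reference=5.0,
        )
        assert cumulative_or(curve, 5.0) == (1.0, 1.0, 1.0)

    def test_hand_exponentials(self):
        curve = ExposureResponseCurve(
            grid=np.array([70.0, 76.0]), cum_log_or=np.array([0.0, 0.25]),
            se=np.array([0.0, 0.07]), reference=70.0,
        )
        or_, lo, hi = cumulative_or(curve, 76.0, level=0.95)
        z = stats.norm.ppf(0.975)
        assert or_ == pytest.approx(math.exp(0.25), rel=1e-12)
        assert lo == pytest.approx(math.exp(0.25 - z * 0.07), rel=1e-12)
        assert hi == pytest.approx(math.exp(0.25 + z * 0.07), rel=1e-12)

    def test_wider_level_widens_interval(self):
        curve = ExposureResponseCurve(
            grid=np.array([70.0, 76.0]), cum_log_or=np.array([0.0, 0.25]),
            se=np.array([0.0, 0.07]), reference=70.0,
        )
        _, lo95, hi95 = cumulative_or(curve, 76.0, level=0.95)
        _, lo99, hi99 = cumulative_or(curve, 76.0, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_outside_grid_rejected(self):
        curve = ExposureResponseCurve(
            grid=np.array([70.0, 76.0]), cum_log_or=np.array([0.0, 0.25]),
            se=np.array([0.0, 0.07]), reference=70.0,
        )
        with pytest.raises(ValueError):
            cumulative_or(curve, 80.0)


class TestCochranQ:
    def test_identical_estimates_no_heterogeneity(self):
        q, df, p = cochran_q([(0.2, 0.1), (0.2, 0.1), (0.2, 0.1)])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_estimate_hand_arithmetic(self):
        # theta = {0.2, 0.0}, se = {0.1, 0.1}: w = 100 each, pooled = 0.1,
        # Q = 100*(0.1)^2 * 2 = 2, df = 1
        q, df, p = cochran_q([(0.2, 0.1), (0.0, 0.1)])
        assert q == pytest.approx(2.0, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)

    def test_scale_law(self):
        q1, _, _ = cochran_q([(0.2, 0.1), (0.0, 0.1)])
        q2, _, _ = cochran_q([(0.2, 1.0), (0.0, 1.0)])
        assert q1 == pytest.approx(100 * q2, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cochran_q([(0.2, 0.1)])
        with pytest.raises(ValueError):
            cochran_q([(0.2, 0.1), (0.1, 0.0)])


def test_subgroup_estimate_invariants():
    est = hl.SubgroupEstimate(label="female", or_point=1.3, ci_low=1.1,
                              ci_high=1.6, n_encounters=800)
    assert est.ci_low <= est.or_point <= est.ci_high
    with pytest.raises(ValueError):
        hl.SubgroupEstimate(label="bad", or_point=1.0, ci_low=1.2,
                            ci_high=1.4, n_encounters=10)
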