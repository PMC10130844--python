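import math

import numpy as np
import pytest

import heatlag as hl
from heatlag.clogit import FitError, conditional_loglik, fit_conditional_logistic

from tests.oracles import (
    brute_force_fit,
    make_stratum,
    naive_conditional_loglik,
    random_small_fixture,
)


def _discordant_pairs(n_case_exposed, n_ref_exposed):
    strata = [make_stratum([1.0], [[0.0]]) for _ in range(n_case_exposed)]
    strata += [make_stratum([0.0], [[1.0]]) for _ in range(n_ref_exposed)]
    return strata


class TestConditionalLoglik:
    def test_beta_zero_is_uniform_probability(self):
        rng = np.random.default_rng(0)
        strata = [
            make_stratum(rng.normal(size=2), rng.normal(size=(m, 2)))
            for m in (1, 2, 3, 4, 4)
        ]
        expected = -sum(math.log(s.rows.shape[0]) for s in strata)
        assert conditional_loglik(np.zeros(2), strata) == pytest.approx(expected)

    def test_stratum_shift_invariance(self):
        rng = np.random.default_rng(1)
        strata = [make_stratum(rng.normal(size=3), rng.normal(size=(3, 3)))]
        beta = rng.normal(size=3)
        base = conditional_loglik(beta, strata)
        shifted = [make_stratum(strata[0].rows[0] + 5.0, strata[0].rows[1:] + 5.0)]
        assert conditional_loglik(beta, shifted) == pytest.approx(base)

    def test_single_stratum_hand_value(self):
        # 1:3 stratum, scalar exposure case=1 refs=0, beta=ln2:
        # ll = ln(e^{ln2} / (e^{ln2} + 3)) = ln(2/5)
        strata = [make_stratum([1.0], [[0.0], [0.0], [0.0]])]
        got = conditional_loglik(np.array([math.log(2.0)]), strata)
        assert got == pytest.approx(math.log(2.0 / 5.0), rel=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        strata = random_small_fixture(rng, n_params=3)
        beta = rng.normal(size=3)
        assert conditional_loglik(beta, strata) == pytest.approx(
            naive_conditional_loglik(beta, strata), rel=1e-10
        )

    def test_dimension_mismatch(self):
        strata = [make_stratum([1.0, 0.0], [[0.0, 1.0]])]
        with pytest.raises(ValueError):
            conditional_loglik(np.zeros(3), strata)


class TestFit:
    def test_discordant_pair_closed_form(self):
        fit = fit_conditional_logistic(_discordant_pairs(10, 5))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(math.log(2.0), abs=1e-8)

    def test_grid_oracle_small_fixture(self):
        rng = np.random.default_rng(3)
        strata = random_small_fixture(rng, max_strata=3, n_params=2)
        fit = fit_conditional_logistic(strata)
        oracle = brute_force_fit(strata, 2)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-4)

    def test_constant_within_stratum_not_identifiable(self):
        strata = [make_stratum([1.0], [[1.0], [1.0]]) for _ in range(5)]
        with pytest.raises(FitError):
            fit_conditional_logistic(strata)

    def test_separation_reported(self):
        # one column always ranks the case strictly above every referent
        rng = np.random.default_rng(4)
        strata = [
            make_stratum([2.0 + rng.random()], [[0.0], [0.5]]) for _ in range(8)
        ]
        with pytest.raises(FitError):
            fit_conditional_logistic(strata)

    def test_shift_invariant_estimates(self):
        rng = np.random.default_rng(5)
        strata = random_small_fixture(rng, n_params=2)
        fit = fit_conditional_logistic(strata)
        shifted = [
            make_stratum(s.rows[0] + [3.0, -7.0], s.rows[1:] + [3.0, -7.0])
            for s in strata
        ]
        fit2 = fit_conditional_logistic(shifted)
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-7)
        np.testing.assert_allclose(fit.cov, fit2.cov, atol=1e-7)

    def test_information_positive_definite_and_cov_symmetric(self):
        rng = np.random.default_rng(6)
        strata = random_small_fixture(rng, n_params=3)
        fit = fit_conditional_logistic(strata)
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)
        assert fit.loglik <= 0.0

    def test_uninformative_strata_counted_not_used(self):
        rng = np.random.default_rng(7)
        strata = random_small_fixture(rng, n_params=2)
        fit0 = fit_conditional_logistic(strata)
        padded = strata + [make_stratum([1.0, 1.0], [[1.0, 1.0], [1.0, 1.0]])]
        fit1 = fit_conditional_logistic(padded)
        np.testing.assert_allclose(fit0.beta, fit1.beta, atol=1e-9)
        assert fit1.n_strata == fit0.n_strata + 1
        assert fit1.n_informative_strata == fit0.n_informative_strata
        # the uninformative stratum contributes exactly -log(3) to loglik
        assert fit1.loglik == pytest.approx(fit0.loglik - math.log(3.0))

    def test_statsmodels_cross_check(self):
        # independent route: statsmodels' conditional likelihood maximizer
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(8)
        for _ in range(5):
            strata = random_small_fixture(rng, n_params=2)
            fit = fit_conditional_logistic(strata)
            y, X, g = [], [], []
            for i, s in enumerate(strata):
                for j, row in enumerate(s.rows):
                    y.append(1 if j == 0 else 0)
                    X.append(row)
                    g.append(i)
            sm_fit = ConditionalLogit(np.array(y), np.array(X), groups=np.array(g)).fit(
                method="newton", tol=1e-12, disp=False
            )
            np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)


def test_fit_result_json_export(tmp_path):
    import json

    rng = np.random.default_rng(9)
    strata = random_small_fixture(rng, n_params=2)
    fit = fit_conditional_logistic(strata)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    doc = json.loads(path.read_text())
    np.testing.assert_allclose(doc["beta"], fit.beta)
    assert doc["converged"] and doc["n_strata"] == fit.n_strata
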