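import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diadino.errors import InvalidArgumentError
from diadino.glms import (
    ModelSpec,
    aicc,
    design_matrix,
    fit_gam_1d,
    fit_glm,
    ols_regression,
    response_amplitude,
    select_model,
)


def factorial_table(seed=0, noise=0.0):
    rows = []
    rng = np.random.default_rng(seed)
    for t, npr, nit in itertools.product(
        (12, 18, 24), (10, 24, 63), (35.2, 88, 352, 880, 1760, 4400)
    ):
        y = 1.0 + 0.5 * t - 0.02 * npr + 0.001 * nit
        rows.append(
            {
                "temperature": t,
                "np_ratio": npr,
                "nitrate": nit,
                "y": y + (rng.normal(0, noise) if noise else 0.0),
            }
        )
    return pd.DataFrame(rows)


class TestAicc:
    def test_hand_formula(self):
        # -2l + 2k = 100 with k = 3, n = 20 -> correction 2*3*4/16 = 1.5
        assert aicc(-47.0, 3, 20) == pytest.approx(101.5)

    def test_large_n_converges_to_aic(self):
        assert aicc(-47.0, 3, 10**9) == pytest.approx(100.0, abs=1e-6)

    def test_k_zero_is_minus_twice_loglik(self):
        assert aicc(-12.5, 0, 10) == pytest.approx(25.0)

    def test_undefined_for_small_n(self):
        with pytest.raises(InvalidArgumentError):
            aicc(-1.0, 5, 6)

    @given(
        l1=st.floats(-100, 100),
        dl=st.floats(0.1, 50),
        k=st.integers(0, 5),
    )
    def test_monotone_in_loglik_and_k(self, l1, dl, k):
        n = 50
        assert aicc(l1 + dl, k, n) < aicc(l1, k, n)
        assert aicc(l1, k + 1, n) > aicc(l1, k, n)


class TestGLM:
    def test_exact_linear_data_recovered(self):
        table = factorial_table()
        fit = fit_glm(table, ModelSpec(response="y", order=1))
        coefs = fit.coefficients["coef"]
        assert coefs["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert coefs["temperature"] == pytest.approx(0.5, abs=1e-10)
        assert coefs["np_ratio"] == pytest.approx(-0.02, abs=1e-10)
        assert coefs["nitrate"] == pytest.approx(0.001, abs=1e-10)
        assert (fit.coefficients["p"] < 1e-8).all()

    def test_intercept_only_model_fits_mean(self):
        table = factorial_table(noise=0.5)
        fit = fit_glm(table, ModelSpec(response="y", factors=(), order=1))
        assert fit.coefficients["coef"]["Intercept"] == pytest.approx(
            table["y"].mean()
        )

    def test_matches_brute_force_normal_equations(self):
        table = factorial_table(noise=1.0, seed=3)
        spec = ModelSpec(response="y", order=2)
        fit = fit_glm(table, spec)
        X = design_matrix(table, spec).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ table["y"].to_numpy())
        assert np.allclose(fit.coefficients["coef"].to_numpy(), beta, atol=1e-8)

    def test_aliased_design_rejected(self):
        table = factorial_table()
        table["nitrate"] = 2.0 * table["temperature"]
        with pytest.raises(InvalidArgumentError, match="aliased|rank"):
            fit_glm(table, ModelSpec(response="y", order=1))

    def test_gamma_log_family_accepted(self):
        table = factorial_table(noise=0.1, seed=5)
        table["y"] = np.exp(table["y"] / 20.0)
        fit = fit_glm(
            table, ModelSpec(response="y", order=1, family_link="gamma_log")
        )
        assert math.isfinite(fit.aicc)


class TestModelSelection:
    @staticmethod
    def _fits(aiccs, interaction_p=None):
        """Build minimal GLMFit-like candidates from AICc values."""
        from diadino.glms import GLMFit

        out = []
        for order, val in aiccs.items():
            terms = ["Intercept", "temperature"]
            ps = [0.5, 0.5]
            if order >= 2:
                terms.append("temperature:np_ratio")
                ps.append(
                    interaction_p.get(order, 0.5) if interaction_p else 0.5
                )
            coef = pd.DataFrame(
                {"coef": 0.0, "se": 1.0, "t": 0.0, "p": ps}, index=terms
            )
            out.append(
                GLMFit(
                    spec=ModelSpec(response="y", order=order),
                    coefficients=coef,
                    loglik=0.0,
                    k=len(terms) + 1,
                    n=50,
                    aicc=val,
                )
            )
        return out

    def test_ten_unit_improvement_wins(self):
        chosen = select_model(self._fits({1: 100.0, 2: 85.0}))
        assert chosen.spec.order == 2

    def test_small_improvement_defers_to_simpler(self):
        chosen = select_model(self._fits({1: 100.0, 2: 95.0}))
        assert chosen.spec.order == 1

    def test_tie_goes_to_simpler(self):
        chosen = select_model(self._fits({1: 100.0, 2: 100.0}))
        assert chosen.spec.order == 1

    def test_significant_interaction_overrides(self):
        chosen = select_model(
            self._fits({1: 100.0, 2: 95.0}, interaction_p={2: 0.01})
        )
        assert chosen.spec.order == 2

    def test_invariant_to_candidate_order(self):
        fits = self._fits({1: 100.0, 2: 95.0, 3: 93.0})
        assert (
            select_model(fits).spec.order
            == select_model(list(reversed(fits))).spec.order
        )

    def test_empty_candidates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_model([])


class TestGAM:
    def test_noiseless_linear_reproduced(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0.0, 10.0, 80))
        fit = fit_gam_1d(x, 2.0 * x)
        assert fit.deviance_explained >= 0.999
        # partial effect equals the line centred over the observations
        line = 2.0 * fit.partial_x
        assert np.allclose(fit.partial_s, line - 2.0 * x.mean(), atol=1e-6)

    def test_heavy_penalty_limits_to_linear_fit(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0.0, 10.0, 60))
        y = np.sin(x) + rng.normal(0, 0.2, 60)
        fit = fit_gam_1d(x, y, lambda_grid=np.array([1e14]))
        assert fit.edf == pytest.approx(2.0, abs=0.01)

    def test_edf_non_increasing_in_lambda(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0.0, 1.0, 60))
        y = np.sin(6 * x) + rng.normal(0, 0.1, 60)
        edfs = [
            fit_gam_1d(x, y, lambda_grid=np.array([lam])).edf
            for lam in (1e-4, 1e-1, 1e2, 1e5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_gcv_choice_beats_linear_limit_on_rss(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0.0, 1.0, 80))
        y = np.sin(6 * x) + rng.normal(0, 0.1, 80)
        free = fit_gam_1d(x, y)
        limit = fit_gam_1d(x, y, lambda_grid=np.array([1e14]))
        assert free.deviance_explained >= limit.deviance_explained

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_gam_1d(np.ones(20), np.arange(20.0))

    def test_white_noise_explains_little(self):
        x = np.sort(np.random.default_rng(42).uniform(0.0, 1.0, 100))
        devs = [
            fit_gam_1d(x, np.random.default_rng(s).normal(size=100)).deviance_explained
            for s in range(40)
        ]
        assert np.median(devs) < 0.15


class TestAmplitude:
    def test_flat_fit_has_zero_amplitude(self):
        x = np.linspace(0, 1, 50)
        fit = fit_gam_1d(x, np.full(50, 3.0))
        assert response_amplitude(fit) == pytest.approx(0.0, abs=1e-8)

    def test_linear_amplitude_is_slope_times_span(self):
        x = np.linspace(0.0, 10.0, 60)
        fit = fit_gam_1d(x, -1.5 * x)
        assert response_amplitude(fit) == pytest.approx(15.0, rel=1e-6)

    def test_invariant_to_constant_shift(self):
        x = np.linspace(0.0, 1.0, 60)
        y = np.sin(4 * x)
        a1 = response_amplitude(fit_gam_1d(x, y))
        a2 = response_amplitude(fit_gam_1d(x, y + 100.0))
        assert a1 == pytest.approx(a2, rel=1e-6)


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_regression(x, 3.0 * x + 1.0)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ols_regression(np.arange(10.0), np.full(10, 2.0))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(0.0)

    def test_matches_normal_equations_on_small_table(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0])
        y = np.array([2.1, 2.9, 5.2, 5.8, 8.1, 8.7])
        fit = ols_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.slope == pytest.approx(beta[1])

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ols_regression(np.ones(5), np.arange(5.0))
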