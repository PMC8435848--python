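import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diadino.dynamics import (
    CommunityParams,
    Trajectory,
    apply_dilution,
    closed_form_logistic,
    detect_steady_state,
    lv_derivative,
    simulate_batch,
    simulate_semicontinuous,
)
from diadino.errors import InvalidArgumentError


def params(**kw):
    base = dict(
        r_diatom=0.8, r_dino=0.45, K_diatom=120.0, K_dino=50.0, alpha=0.5, beta=0.3
    )
    base.update(kw)
    return CommunityParams(**base)


class TestDerivative:
    def test_reduces_to_logistic_without_partner(self):
        p = params(alpha=2.0)
        d1, _ = lv_derivative(30.0, 0.0, p)
        assert d1 == pytest.approx(0.8 * 30 * (120 - 30) / 120, rel=1e-12)

    def test_zero_at_carrying_capacity(self):
        d1, d2 = lv_derivative(120.0, 0.0, params())
        assert d1 == 0.0 and d2 == 0.0

    def test_interaction_cancels_growth(self):
        # K1 - N1 - alpha N2 = 100 - 50 - 2*25 = 0
        p = params(r_diatom=1.0, K_diatom=100.0, alpha=2.0)
        d1, _ = lv_derivative(50.0, 25.0, p)
        assert d1 == pytest.approx(0.0, abs=1e-12)

    def test_rejects_non_finite_densities(self):
        with pytest.raises(InvalidArgumentError):
            lv_derivative(float("nan"), 1.0, params())


class TestClosedFormLogistic:
    def test_boundary_values(self):
        assert closed_form_logistic(0.5, 100.0, 7.0, 0.0) == pytest.approx(7.0)
        assert closed_form_logistic(0.5, 100.0, 1.0, 1e4) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        e5 = math.exp(5.0)
        expected = 100.0 * e5 / (100.0 + e5 - 1.0)
        assert closed_form_logistic(0.5, 100.0, 1.0, 10.0) == pytest.approx(
            expected, rel=1e-12
        )


class TestBatchSimulation:
    @pytest.mark.parametrize("r", [0.2, 0.6, 1.2])
    def test_matches_logistic_oracle_without_interaction(self, r):
        p = params(r_diatom=r, alpha=0.0, beta=0.0)
        traj = simulate_batch(p, 1.0, 0.0, 30)
        days = traj.df["day"].to_numpy()
        exact = closed_form_logistic(r, 120.0, 1.0, days)
        rel = np.abs(traj.df["n_diatom"].to_numpy() - exact) / exact
        assert rel.max() < 1e-6

    def test_absent_species_stays_absent(self):
        traj = simulate_batch(params(), 1.0, 0.0, 10)
        assert (traj.df["n_dino"] == 0.0).all()

    def test_monotone_below_capacity(self):
        traj = simulate_batch(params(alpha=0.0, beta=0.0), 1.0, 1.0, 20)
        assert (np.diff(traj.df["n_diatom"].to_numpy()) >= 0).all()
        assert (np.diff(traj.df["n_dino"].to_numpy()) >= 0).all()

    def test_step_halving_convergence(self):
        p = params()
        a = simulate_batch(p, 1.0, 1.0, 15, step=0.02)
        b = simulate_batch(p, 1.0, 1.0, 15, step=0.01)
        rel = np.abs(a.df["n_diatom"] - b.df["n_diatom"]) / b.df["n_diatom"].clip(
            lower=1e-12
        )
        assert rel.max() < 1e-6

    def test_independence_when_uncoupled(self):
        p = params(alpha=0.0, beta=0.0)
        t1 = simulate_batch(p, 1.0, 1.0, 15)
        t2 = simulate_batch(p, 1.0, 5.0, 15)
        assert t1.df["n_diatom"].tolist() == t2.df["n_diatom"].tolist()

    def test_densities_never_negative(self):
        p = params(alpha=3.0, beta=2.0)
        traj = simulate_batch(p, 50.0, 50.0, 30)
        assert (traj.df[["n_diatom", "n_dino"]] >= 0).all().all()


class TestDilution:
    def test_identity_and_halving(self):
        assert apply_dilution((10.0, 4.0), 0.0) == (10.0, 4.0)
        n1, n2 = apply_dilution((10.0, 4.0), 0.5)
        assert (float(n1), float(n2)) == (5.0, 2.0)

    @given(d1=st.floats(0.0, 0.95), d2=st.floats(0.0, 0.95))
    def test_composition_of_dilutions(self, d1, d2):
        a = apply_dilution(apply_dilution((10.0, 4.0), d1), d2)
        combined = 1 - (1 - d1) * (1 - d2)
        b = apply_dilution((10.0, 4.0), combined)
        assert float(a[0]) == pytest.approx(float(b[0]), rel=1e-12)

    def test_rejects_full_replacement(self):
        with pytest.raises(InvalidArgumentError):
            apply_dilution((1.0, 1.0), 1.0)


class TestSemicontinuous:
    def test_d_zero_equals_batch(self):
        p = params()
        batch = simulate_batch(p, 1.0, 1.0, 10)
        semi = simulate_semicontinuous(p, (1.0, 1.0), 0.0, 10)
        pre = semi.pre_dilution_series()
        merged = batch.df.merge(pre, on="day", suffixes=("_b", "_s"))
        assert np.allclose(merged["n_diatom_b"], merged["n_diatom_s"], rtol=1e-12)

    def test_steady_state_growth_balances_dilution(self):
        # monoculture daily map converges; at the fixed point the per-day
        # log growth equals -ln(1 - D)
        p = params(alpha=0.0, beta=0.0)
        D = 0.15
        traj = simulate_semicontinuous(p, (50.0, 0.0), D, 80)
        post = traj.post_dilution_series()["n_diatom"].to_numpy()
        pre = traj.pre_dilution_series()["n_diatom"].to_numpy()
        g = math.log(pre[-1] / post[-2])
        assert g == pytest.approx(-math.log(1 - D), abs=1e-6)

    def test_washout_when_growth_cannot_balance(self):
        # r < -ln(1-D): dilution removes more than growth restores
        p = CommunityParams(0.1, 0.4, 1e9, 50.0, 0.0, 0.0)
        D = 0.4  # -ln(0.6) ~ 0.51 > r
        traj = simulate_semicontinuous(p, (10.0, 0.0), D, 60)
        assert traj.post_dilution_series()["n_diatom"].iloc[-1] < 1e-4

    def test_increasing_alpha_never_raises_diatom_steady_density(self):
        finals = []
        for alpha in np.linspace(-1.0, 2.0, 7):
            p = params(alpha=float(alpha))
            traj = simulate_semicontinuous(p, (30.0, 20.0), 0.1, 40)
            finals.append(traj.post_dilution_series()["n_diatom"].iloc[-1])
        assert (np.diff(finals) <= 1e-9).all()


class TestSteadyStateDetection:
    @staticmethod
    def _traj_from_post(days, n1, n2=None):
        import pandas as pd

        n2 = np.zeros_like(np.asarray(n1, dtype=float)) if n2 is None else n2
        df = pd.DataFrame(
            {
                "day": days,
                "phase": "semicontinuous",
                "post_dilution": True,
                "n_diatom": n1,
                "n_dino": n2,
            }
        )
        return Trajectory(df, D=0.1)

    def test_constant_series_detected_at_first_eligible_day(self):
        days = np.arange(10.0)
        traj = self._traj_from_post(days, np.full(10, 5.0))
        assert detect_steady_state(traj, window=5, cv_tol=0.05) == 4

    def test_exponential_growth_never_steady(self):
        days = np.arange(15.0)
        traj = self._traj_from_post(days, 2.0 * np.exp(0.5 * days))
        assert detect_steady_state(traj, window=5, cv_tol=0.05) is None

    def test_simulated_monoculture_reaches_steady_state(self):
        p = params(alpha=0.0, beta=0.0)
        traj = simulate_semicontinuous(p, (50.0, 0.0), 0.15, 40)
        day = detect_steady_state(traj, window=5, cv_tol=0.05)
        assert day is not None and day <= 40

    def test_short_trajectory_rejected(self):
        traj = self._traj_from_post(np.arange(3.0), np.full(3, 5.0))
        with pytest.raises(InvalidArgumentError):
            detect_steady_state(traj, window=5, cv_tol=0.05)

    def test_window_below_three_rejected(self):
        traj = self._traj_from_post(np.arange(10.0), np.full(10, 5.0))
        with pytest.raises(InvalidArgumentError):
            detect_steady_state(traj, window=2, cv_tol=0.05)
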