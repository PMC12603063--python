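"""Estimation: noiseless self-consistency, grid-search oracles, the
normal-equations oracle for the conditionally linear closeness fit, and
goodness-of-fit arithmetic."""

import numpy as np
import pytest

from grouplearn.closeness_models import ClosenessParams, predict_closeness_change
from grouplearn.fitting import (
    _bounded_ols,
    _closeness_design,
    fit_closeness,
    fit_learning,
    fits_to_frame,
    goodness_of_fit,
)
from grouplearn.learning_models import LearningParams, simulate_learning
from grouplearn.synthetic_data import SessionData
from grouplearn.task_design import INGROUP, make_schedule
from grouplearn.validation import (
    _simulate_closeness_session,
    _simulate_expectancy_session,
)


def _session_noiseless(schedule, params):
    rng = np.random.default_rng(0)
    return _simulate_expectancy_session(schedule, params, 0.0, rng)


class TestFitLearning:
    def test_noiseless_m1_recovery(self, schedule96):
        truth = LearningParams(0.4, 0.4, 0.4, 0.4, beta=1.0, v0_ingroup=0.5, v0_outgroup=0.5)
        fit = fit_learning(_session_noiseless(schedule96, truth), "M1", n_restarts=10, seed=0)
        assert fit.params["alpha"] == pytest.approx(0.4, abs=1e-4)
        assert fit.params["beta"] == pytest.approx(1.0, abs=1e-4)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_m3_recovery(self, schedule96):
        truth = LearningParams(0.6, 0.15, 0.35, 0.8, beta=1.4, v0_ingroup=0.4, v0_outgroup=0.7)
        fit = fit_learning(_session_noiseless(schedule96, truth), "M3", n_restarts=10, seed=0)
        for name, val in (
            ("alpha_in_pos", 0.6),
            ("alpha_in_neg", 0.15),
            ("alpha_out_pos", 0.35),
            ("alpha_out_neg", 0.8),
            ("beta", 1.4),
        ):
            assert fit.params[name] == pytest.approx(val, abs=1e-3)

    def test_grid_search_oracle_m1(self):
        # optimizer must do at least as well as a dense (alpha, beta) grid
        sched = make_schedule(1, 8, 0.5, seed=3)  # 8 trials for a tiny surface
        truth = LearningParams(0.5, 0.5, 0.5, 0.5, beta=1.2, v0_ingroup=0.5, v0_outgroup=0.5)
        rng = np.random.default_rng(2)
        session = _simulate_expectancy_session(sched, truth, 0.2, rng)
        fit = fit_learning(session, "M1", n_restarts=10, seed=0)

        obs = session.expectancy
        is_in = sched.is_ingroup
        first_in, first_out = int(np.argmax(is_in)), int(np.argmax(~is_in))
        mask = np.ones(8, dtype=bool)
        mask[[first_in, first_out]] = False

        def sse(alpha, beta):
            p = LearningParams(alpha, alpha, alpha, alpha, beta, obs[first_in], obs[first_out])
            traj = simulate_learning(sched, p, "M1")
            resid = beta * traj.values[mask] - obs[mask]
            return resid @ resid

        grid = min(
            sse(a, b) for a in np.linspace(0, 1, 50) for b in np.linspace(0.01, 3, 50)
        )
        assert fit.sse <= grid + 1e-9

    def test_aic_identity_and_bounds(self, schedule96, m3_params):
        session = _session_noiseless(schedule96, m3_params)
        fit = fit_learning(session, "M2", n_restarts=5, seed=1)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-10)
        assert fit.k == 3
        assert 0 <= fit.params["alpha_in"] <= 1
        assert 0 < fit.params["beta"] <= 3
        assert fit.r2 <= 1

    def test_monotone_improvement_in_restarts(self, schedule96):
        truth = LearningParams(0.7, 0.1, 0.2, 0.9, beta=2.0, v0_ingroup=0.3, v0_outgroup=0.8)
        rng = np.random.default_rng(7)
        session = _simulate_expectancy_session(schedule96, truth, 0.2, rng)
        sses = [
            fit_learning(session, "M3", n_restarts=n, seed=11).sse for n in (1, 3, 10)
        ]
        assert sses[1] <= sses[0] + 1e-12
        assert sses[2] <= sses[1] + 1e-12

    def test_deterministic_under_seed(self, schedule96, m3_params):
        rng = np.random.default_rng(3)
        session = _simulate_expectancy_session(schedule96, m3_params, 0.15, rng)
        f1 = fit_learning(session, "M3", n_restarts=5, seed=42)
        f2 = fit_learning(session, "M3", n_restarts=5, seed=42)
        assert f1.params == f2.params and f1.sse == f2.sse

    def test_constant_series_warns(self, schedule96):
        zeros = np.zeros(96)
        session = SessionData(
            participant="flat",
            frame="gain",
            schedule=schedule96,
            expectancy=np.full(96, 0.5),
            closeness_in=zeros,
            closeness_out=zeros,
            impression_pre_in=5,
            impression_pre_out=5,
            impression_post_in=5,
            impression_post_out=5,
            identification=4,
        )
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit_learning(session, "M1", n_restarts=2, seed=0)

    def test_nested_aic_penalty_in_expectation(self):
        # parent (M3) fit to M1-generated data pays the complexity penalty:
        # on average AIC_M3 >= AIC_M1, and never better than 2*dk in loglik
        gaps = []
        for i in range(12):
            sched = make_schedule(4, 24, 0.75, seed=500 + i)
            a = 0.2 + 0.05 * i
            truth = LearningParams(a, a, a, a, beta=1.0, v0_ingroup=0.5, v0_outgroup=0.5)
            rng = np.random.default_rng(900 + i)
            session = _simulate_expectancy_session(sched, truth, 0.15, rng)
            f1 = fit_learning(session, "M1", n_restarts=5, seed=i)
            f3 = fit_learning(session, "M3", n_restarts=5, seed=i)
            assert f3.aic >= f1.aic - 2 * (f3.k - f1.k) - 1e-6
            gaps.append(f3.aic - f1.aic)
        assert np.mean(gaps) > 0


class TestFitCloseness:
    def test_noiseless_c2_exact_recovery(self, schedule96, m3_params):
        truth = ClosenessParams(w0=0.0, w_pos=2.0, w_neg=-3.0, gamma=0.5)
        rng = np.random.default_rng(0)
        session, traj = _simulate_closeness_session(schedule96, truth, 0.0, rng)
        fit = fit_closeness(session, traj, "C2", INGROUP, n_restarts=5, seed=0)
        assert fit.params["w0"] == pytest.approx(0.0, abs=1e-4)
        assert fit.params["w_pos"] == pytest.approx(2.0, abs=1e-4)
        assert fit.params["w_neg"] == pytest.approx(-3.0, abs=1e-4)
        assert fit.params["gamma"] == pytest.approx(0.5, abs=1e-4)

    def test_profile_step_matches_normal_equations(self, schedule96):
        # for fixed gamma the weights are an OLS problem; check the
        # package's linear solve against (X'X)^{-1} X'y
        truth = ClosenessParams(w0=1.0, w_pos=4.0, w_neg=-6.0, gamma=0.7)
        rng = np.random.default_rng(5)
        session, traj = _simulate_closeness_session(schedule96, truth, 1.0, rng)
        y = np.diff(session.closeness_in)
        pe = np.ascontiguousarray(traj.pe_series(INGROUP))
        X = _closeness_design(pe, 0.7, "C2", len(y))
        coef, _ = _bounded_ols(X, y, [(0, 10), (-10, 10), (-10, 10)])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-8)

    def test_noisy_recovery_close_to_truth(self, schedule96):
        truth = ClosenessParams(w0=2.0, w_pos=5.0, w_neg=-7.0, gamma=0.6)
        rng = np.random.default_rng(8)
        session, traj = _simulate_closeness_session(schedule96, truth, 1.0, rng)
        fit = fit_closeness(session, traj, "C2", INGROUP, n_restarts=5, seed=0)
        assert fit.params["w_pos"] == pytest.approx(5.0, abs=2.0)
        assert fit.params["w_neg"] == pytest.approx(-7.0, abs=2.0)
        assert fit.params["gamma"] == pytest.approx(0.6, abs=0.2)

    def test_c1_nested_in_c2(self, schedule96):
        truth = ClosenessParams(w0=1.0, w_pos=3.0, w_neg=3.0, gamma=0.4)
        rng = np.random.default_rng(4)
        session, traj = _simulate_closeness_session(schedule96, truth, 0.5, rng)
        f1 = fit_closeness(session, traj, "C1", INGROUP, n_restarts=5, seed=0)
        f2 = fit_closeness(session, traj, "C2", INGROUP, n_restarts=5, seed=0)
        assert f2.sse <= f1.sse + 1e-9
        assert f1.k == 3 and f2.k == 4

    def test_length_mismatch_rejected(self, schedule96, m3_params):
        rng = np.random.default_rng(0)
        session, traj = _simulate_closeness_session(schedule96, ClosenessParams(0, 1, 1, 0.5), 0.5, rng)
        short = make_schedule(1, 24, 0.75, seed=0)
        traj_short = simulate_learning(short, m3_params, "M3")
        with pytest.raises(ValueError, match="length"):
            fit_closeness(session, traj_short, "C2", INGROUP)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        g = goodness_of_fit([1, 2, 3.0], [1, 2, 3.0])
        assert g["r2"] == pytest.approx(1.0) and g["mse"] == pytest.approx(0.0)

    def test_constant_shift_keeps_correlation(self):
        g = goodness_of_fit([1, 2, 3.0], [1.5, 2.5, 3.5])
        assert g["r2"] == pytest.approx(1.0)
        assert g["mse"] == pytest.approx(0.25)

    def test_hand_computed_pearson(self):
        obs = np.array([1, 2, 3, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        # textbook formula, computed independently
        r = np.sum((obs - obs.mean()) * (pred - pred.mean())) / np.sqrt(
            np.sum((obs - obs.mean()) ** 2) * np.sum((pred - pred.mean()) ** 2)
        )
        g = goodness_of_fit(obs, pred)
        assert g["r2"] == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_flagged(self):
        g = goodness_of_fit([2, 2, 2.0], [1, 2, 3.0])
        assert np.isnan(g["r2"])

    def test_sse_variant(self):
        g = goodness_of_fit([1, 2, 3.0], [1.5, 2.5, 3.5], method="sse")
        assert g["r2"] == pytest.approx(1 - 0.75 / 2.0)

    def test_rejects_mismatched(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2.0], [1.0])


def test_fits_to_frame_layout(schedule96, m3_params):
    rng = np.random.default_rng(1)
    session = _simulate_expectancy_session(schedule96, m3_params, 0.1, rng)
    fits = [fit_learning(session, m, n_restarts=2, seed=0) for m in ("M1", "M2")]
    df = fits_to_frame(fits)
    assert {"participant", "model", "aic", "r2", "sse", "loglik", "k"} <= set(df.columns)
    assert len(df) == 2
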