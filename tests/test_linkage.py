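"""Stepwise selection, moderation, influence diagnostics and the
bias-identification correlation: known-truth simulations and null
calibrations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grouplearn.linkage import (
    bias_identification_correlation,
    influence_filter,
    moderation,
    stepwise_regression,
)


def _candidates(rng, n, p, names=None):
    X = pd.DataFrame(rng.standard_normal((n, p)))
    X.columns = names or [f"x{i + 1}" for i in range(p)]
    return X


class TestStepwise:
    def test_selects_single_true_predictor(self):
        rng = np.random.default_rng(0)
        X = _candidates(rng, 50, 8)
        y = 2.0 * X["x1"] + 0.3 * rng.standard_normal(50)
        res = stepwise_regression(X, y)
        assert res.selected_predictors == ["x1"]
        coef = res.coefficients.set_index("term").loc["x1", "coef"]
        assert coef == pytest.approx(2.0, abs=0.2)

    def test_single_candidate_equal_to_outcome(self):
        rng = np.random.default_rng(1)
        X = _candidates(rng, 30, 1)
        res = stepwise_regression(X, X["x1"].to_numpy())
        assert res.selected_predictors == ["x1"]
        row = res.coefficients.set_index("term").loc["x1"]
        assert row["coef"] == pytest.approx(1.0, abs=1e-8)
        assert row["p"] < 1e-12

    def test_thresholds_one_give_full_model(self):
        rng = np.random.default_rng(2)
        X = _candidates(rng, 40, 4)
        y = rng.standard_normal(40)
        res = stepwise_regression(X, y, entry_p=1.0, removal_p=1.0)
        assert sorted(res.selected_predictors) == ["x1", "x2", "x3", "x4"]

    def test_entry_zero_gives_empty_model(self):
        rng = np.random.default_rng(3)
        X = _candidates(rng, 40, 4)
        y = 3 * X["x2"] + 0.1 * rng.standard_normal(40)
        res = stepwise_regression(X, y, entry_p=0.0)
        assert res.selected_predictors == []

    def test_null_selection_rate_calibrated(self):
        # pure-noise outcome: P(select nothing) ~ (1 - entry_p)^p for
        # independent candidates
        rng = np.random.default_rng(4)
        p, n, sims = 3, 30, 400
        empty = 0
        for _ in range(sims):
            X = _candidates(rng, n, p)
            y = rng.standard_normal(n)
            if not stepwise_regression(X, y).selected_predictors:
                empty += 1
        expected = (1 - 0.05) ** p
        assert empty / sims == pytest.approx(expected, abs=0.06)

    def test_rejects_too_few_observations(self):
        rng = np.random.default_rng(5)
        X = _candidates(rng, 8, 6)
        with pytest.raises(ValueError, match="observations"):
            stepwise_regression(X, rng.standard_normal(8))

    def test_collinear_candidates_warn_and_drop(self):
        rng = np.random.default_rng(6)
        X = _candidates(rng, 40, 2)
        X["x3"] = X["x1"] * 2.0  # exact duplicate direction
        y = X["x1"] + 0.2 * rng.standard_normal(40)
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(X, y)
        assert "x3" not in res.selected_predictors


class TestModeration:
    def test_pure_interaction_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        m = rng.standard_normal(60)
        res = moderation(x, m, x * m)
        assert res.interaction["coef"] == pytest.approx(1.0, abs=1e-8)
        assert res.interaction["p"] < 1e-12

    def test_binary_moderator_simple_slopes(self):
        rng = np.random.default_rng(1)
        n = 80
        x = rng.standard_normal(n)
        frame = np.repeat([0.0, 1.0], n // 2)
        # slope -1 in frame 0, 0 in frame 1
        y = (-1.0 + 1.0 * frame) * x + 0.2 * rng.standard_normal(n)
        res = moderation(x, frame, y, x_name="w_neg_in", moderator_name="frame")
        slopes = res.simple_slopes.set_index("at")["slope"]
        assert slopes["level_0"] == pytest.approx(-1.0, abs=0.15)
        assert slopes["level_1"] == pytest.approx(0.0, abs=0.15)
        assert res.interaction["p"] < 1e-6

    def test_continuous_moderator_probe_points(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        m = 4 + 1.5 * rng.standard_normal(100)
        y = x * (m - m.mean()) + 0.3 * rng.standard_normal(100)
        res = moderation(x, m, y)
        at = set(res.simple_slopes["at"])
        assert at == {"mean_minus_1sd", "mean", "mean_plus_1sd"}
        lo = res.simple_slopes.set_index("at").loc["mean_minus_1sd", "slope"]
        hi = res.simple_slopes.set_index("at").loc["mean_plus_1sd", "slope"]
        assert lo < hi  # slope increases with the moderator

    def test_affine_rescaling_of_x(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        m = rng.standard_normal(50)
        y = 2 * x + x * m + 0.1 * rng.standard_normal(50)
        r1 = moderation(x, m, y)
        r2 = moderation(3 * x + 5, m, y)  # interaction coef scales by 1/3
        assert r2.interaction["coef"] == pytest.approx(r1.interaction["coef"] / 3, abs=1e-8)

    def test_type_one_error_rate_nominal(self):
        rng = np.random.default_rng(4)
        hits = 0
        sims = 400
        for _ in range(sims):
            x = rng.standard_normal(40)
            m = rng.standard_normal(40)
            cov = pd.DataFrame({"c1": rng.standard_normal(40)})
            y = 1.5 * cov["c1"].to_numpy() + rng.standard_normal(40)
            res = moderation(x, m, y, covariates=cov)
            hits += res.interaction["p"] < 0.05
        assert 0.02 <= hits / sims <= 0.09

    def test_zero_variance_moderator_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="variance"):
            moderation(rng.standard_normal(20), np.ones(20), rng.standard_normal(20))

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="n > 10"):
            moderation(rng.standard_normal(8), rng.standard_normal(8), rng.standard_normal(8))


class TestModerationOnSyntheticStudy:
    def test_identification_attenuates_loss_frame_association(self):
        # loss-frame population: negative w_neg_in slope at low
        # identification, attenuated at high identification
        from grouplearn.synthetic_data import generate_study

        sessions = generate_study(n_agents=120, frame_split=0.0, seed=21)
        w = np.array([s.profile.closeness_in.w_neg for s in sessions])
        ident = np.array([s.identification for s in sessions])
        change = np.array([s.intergroup_impression_change for s in sessions])
        res = moderation(w, ident, change, x_name="w_neg_in", moderator_name="identification")
        assert res.interaction["coef"] > 0
        slopes = res.simple_slopes.set_index("at")["slope"]
        assert slopes["mean_minus_1sd"] < 0
        assert slopes["mean_plus_1sd"] > slopes["mean_minus_1sd"]


class TestInfluence:
    def _fit(self, x, y):
        return sm.OLS(y, sm.add_constant(x)).fit()

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = 2 * x + 0.3 * rng.standard_normal(40)
        y[7] += 25.0  # spike-in
        res = influence_filter(self._fit(x, y))
        assert 7 in res.flagged
        # the refit without the outlier recovers the clean slope
        slope = res.robustness.set_index("term").iloc[1]["coef"]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_clean_data_rarely_flagged(self):
        rng = np.random.default_rng(1)
        frac = []
        for _ in range(50):
            x = rng.standard_normal(60)
            y = x + 0.5 * rng.standard_normal(60)
            res = influence_filter(self._fit(x, y))
            frac.append(len(res.flagged) / 60)
        assert np.mean(frac) < 0.15  # standard cutoffs trip on few points

    def test_no_flags_returns_original_fit(self):
        # equally spaced x with tiny symmetric residuals trips no cutoff
        x = np.linspace(-1, 1, 24)
        y = 1.0 + 2.0 * x + 0.01 * np.sin(7 * x)
        fit = self._fit(x, y)
        res = influence_filter(fit)
        if not res.flagged:
            assert res.model_fit is fit
        np.testing.assert_allclose(
            res.robustness["coef"].to_numpy()[: 2 if not res.flagged else None][:2],
            np.asarray(fit.params)[:2],
            atol=0.05,
        )

    def test_minimal_sample_size_runs(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5)  # n = k + 3 with k = 2
        y = x + 0.1 * rng.standard_normal(5)
        res = influence_filter(self._fit(x, y))
        assert res.robustness is not None


class TestBiasIdentification:
    def test_hand_built_five_row_table(self):
        df = pd.DataFrame(
            {
                "identification": [2.0, 3.0, 4.0, 5.0, 6.0],
                "impression_pre_in": [5.0, 5.5, 6.0, 6.5, 7.5],
                "impression_pre_out": [5.0, 5.2, 5.4, 5.6, 5.8],
            }
        )
        bias = df.impression_pre_in - df.impression_pre_out  # 0, .3, .6, .9, 1.7
        ident = df.identification
        r_hand = float(
            np.sum((ident - ident.mean()) * (bias - bias.mean()))
            / np.sqrt(np.sum((ident - ident.mean()) ** 2) * np.sum((bias - bias.mean()) ** 2))
        )
        out = bias_identification_correlation(df)
        assert out["r"] == pytest.approx(r_hand, abs=1e-12)
        assert out["n"] == 5

    def test_synthetic_population_positive_correlation(self):
        from grouplearn.synthetic_data import sample_population

        pop = sample_population(120, 0.5, "western", seed=10)
        df = pd.DataFrame(
            {
                "identification": [a.identification for a in pop],
                "impression_pre_in": [a.impression_pre_in for a in pop],
                "impression_pre_out": [a.impression_pre_out for a in pop],
            }
        )
        out = bias_identification_correlation(df)
        assert out["r"] > 0.05  # same direction/order as the r ~ 0.26 target
        assert out["rho"] > 0.0

    def test_constant_identification_degenerate(self):
        df = pd.DataFrame(
            {
                "identification": [4.0] * 6,
                "impression_pre_in": [5, 6, 7, 5, 6, 7.0],
                "impression_pre_out": [5, 5, 5, 5, 5, 5.0],
            }
        )
        out = bias_identification_correlation(df)
        assert out["degenerate"] and np.isnan(out["r"])

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame(
            {"identification": [1, 2.0], "impression_pre_in": [5, 6.0], "impression_pre_out": [5, 5.0]}
        )
        with pytest.raises(ValueError):
            bias_identification_correlation(df)
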