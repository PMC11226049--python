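"""Supermodel fitting: oracle equivalence, parameter recovery, predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import landmarkpred as lp
from landmarkpred.models import coefficient_table, evaluate_dynamic_coefficient

ZERO_HR = {k: 0.0 for k in ["age", "sex", "etoh", "biliary", "chol", "meldna", "albumin", "decomp", "hcc"]}


def binary_effect_params(seed, n=2000, log_hr=0.7, censoring_hazard=0.15):
    """One binary covariate (etoh) drives an exponential hazard; all else inert."""
    hr = dict(ZERO_HR)
    hr["etoh"] = log_hr
    return lp.CohortParams(
        n_subjects=n,
        seed=seed,
        log_hr=hr,
        hazard_centers={},
        baseline_hazard=0.25,
        censoring_hazard=censoring_hazard,
        admin_end=6.0,
        p_etoh=0.5,
        visit_spacing=1.0,
        visit_jitter=0.2,
    )


def single_landmark_stack(cohort, covariates, tau=3.0):
    grid = lp.LandmarkGrid(times=np.array([0.0]), tau=tau)
    return lp.stack_landmark_datasets(grid, cohort, covariates=covariates)


def manual_pm_model(params_dict, covariates, degree=2, tau=3.0):
    names = list(params_dict)
    return lp.FittedSupermodel(
        family="PM",
        covariates=covariates,
        degree=degree,
        time_scale=5.0,
        tau=tau,
        link="identity",
        params=pd.Series(params_dict),
        cov=pd.DataFrame(np.eye(len(names)) * 1e-4, index=names, columns=names),
    )


class TestGEE:
    def make_stacked(self, x, y, ell=0.0):
        return pd.DataFrame(
            {"subject_id": np.arange(len(x)), "landmark": ell, "x": x, "pseudo": y}
        )

    def test_exact_recovery_when_pseudo_values_are_linear(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 1.5 + 2.0 * x
        m = lp.fit_gee_supermodel(self.make_stacked(x, y), ["x"], tau=3.0, degree=0)
        assert m.params["Intercept"] == pytest.approx(1.5, abs=1e-10)
        assert m.params["x"] == pytest.approx(2.0, abs=1e-10)

    def test_zero_variance_covariate_is_rank_error(self):
        x = np.ones(5)
        with pytest.raises(ValueError, match="rank"):
            lp.fit_gee_supermodel(self.make_stacked(x, x * 2.0), ["x"], tau=3.0, degree=0)

    def test_matches_ols_on_unclustered_data(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=50)
        y = 0.5 - 1.2 * x + rng.normal(size=50)
        m = lp.fit_gee_supermodel(self.make_stacked(x, y), ["x"], tau=3.0, degree=0)
        X = sm.add_constant(x)
        ols = sm.OLS(y, X).fit()
        assert m.params.to_numpy() == pytest.approx(ols.params, abs=1e-10)

    def test_missing_pseudo_column_rejected(self):
        df = self.make_stacked(np.arange(4.0), np.arange(4.0)).drop(columns="pseudo")
        with pytest.raises(ValueError, match="pseudo"):
            lp.fit_gee_supermodel(df, ["x"], tau=3.0)

    def test_recovers_true_conditional_rmst_difference(self):
        params = binary_effect_params(seed=101)
        cohort = lp.simulate_cohort(params)
        stacked = single_landmark_stack(cohort, ["etoh"])
        with_po = lp.attach_pseudo_outcomes(stacked, 3.0, kind="mean")
        m = lp.fit_gee_supermodel(with_po, ["etoh"], tau=3.0, degree=0)
        path = lambda v: pd.DataFrame({"time": [0.0], "etoh": [v]})
        truth = lp.true_conditional_rmst(params, path(1), 0.0, 3.0) - lp.true_conditional_rmst(
            params, path(0), 0.0, 3.0
        )
        se = np.sqrt(m.cov.loc["etoh", "etoh"])
        assert abs(m.params["etoh"] - truth) < 3 * se


class TestCox:
    def brute_force_log_hr(self, entry, exit_, event, x):
        """Maximize the written delayed-entry partial likelihood numerically.

        The log-likelihood sums, over event times, the linear predictor
        minus the log of the risk-set sum; its unique maximum is located by
        bracketing the score (per-event covariate minus risk-set weighted
        mean) to full double precision.
        """

        def score(beta):
            s = 0.0
            for i in np.flatnonzero(event):
                risk = (entry < exit_[i]) & (exit_ >= exit_[i])
                w = np.exp(beta * x[risk])
                s += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return s

        return optimize.brentq(score, -5.0, 5.0, xtol=1e-13)

    def tiny_stacked(self):
        return pd.DataFrame(
            {
                "subject_id": [1, 2, 3],
                "landmark": 0.0,
                "x": [0.0, 1.0, 0.5],
                "entry": 0.0,
                "exit": [1.0, 2.0, 3.0],
                "event_window": [1, 1, 0],
            }
        )

    def test_matches_brute_force_partial_likelihood(self):
        df = self.tiny_stacked()
        m = lp.fit_cox_supermodel(df, ["x"], tau=3.0, degree=0)
        expected = self.brute_force_log_hr(
            df["entry"].to_numpy(),
            df["exit"].to_numpy(),
            df["event_window"].to_numpy(),
            df["x"].to_numpy(),
        )
        assert m.params["x"] == pytest.approx(expected, abs=1e-8)

    def test_delayed_entry_matches_brute_force(self):
        df = pd.DataFrame(
            {
                "subject_id": [1, 2, 3, 4, 5],
                "landmark": 1.0,
                "x": [0.0, 1.0, 0.5, 1.0, 0.0],
                "entry": 1.0,
                "exit": [1.5, 2.0, 2.5, 3.5, 4.0],
                "event_window": [1, 0, 1, 1, 0],
            }
        )
        m = lp.fit_cox_supermodel(df, ["x"], tau=3.0, degree=0)
        expected = self.brute_force_log_hr(
            df["entry"].to_numpy(),
            df["exit"].to_numpy(),
            df["event_window"].to_numpy(),
            df["x"].to_numpy(),
        )
        assert m.params["x"] == pytest.approx(expected, abs=1e-8)

    def test_no_events_rejected(self):
        df = self.tiny_stacked()
        df["event_window"] = 0
        with pytest.raises(ValueError, match="events"):
            lp.fit_cox_supermodel(df, ["x"], tau=3.0, degree=0)

    def test_two_group_exponential_recovery(self):
        params = binary_effect_params(seed=77)
        cohort = lp.simulate_cohort(params)
        stacked = single_landmark_stack(cohort, ["etoh"])
        m = lp.fit_cox_supermodel(stacked, ["etoh"], tau=3.0, degree=0)
        se = np.sqrt(m.cov.loc["etoh", "etoh"])
        assert abs(m.params["etoh"] - 0.7) < 3 * se

    def test_baseline_cumhaz_with_zero_covariate_is_nelson_aalen_like(self):
        # all-zero design is rank deficient by construction, so fit with a
        # balanced binary covariate whose estimate is ~0 and check the
        # baseline against the Breslow increments d/n at the event times
        df = pd.DataFrame(
            {
                "subject_id": np.arange(8),
                "landmark": 0.0,
                "x": [0, 1] * 4,
                "entry": 0.0,
                "exit": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0],
                "event_window": [1, 1, 1, 1, 0, 0, 0, 0],
            }
        )
        m = lp.fit_cox_supermodel(df, ["x"], tau=4.0, degree=0)
        assert m.params["x"] == pytest.approx(0.0, abs=1e-6)
        # Breslow increments with beta=0: 2/8 at t=1, 2/6 at t=2
        assert m._cumhaz_at(1.5)[0] == pytest.approx(2 / 8, rel=1e-4)
        assert m._cumhaz_at(2.5)[0] == pytest.approx(2 / 8 + 2 / 6, rel=1e-4)


class TestDynamicCoefficient:
    PM_DECOMP = {"Intercept": 2.833, "decomp": -0.151, "decomp:t": 0.640, "decomp:t2": -0.671}

    def test_decompensation_effect_at_year_five(self):
        m = manual_pm_model(self.PM_DECOMP, ["decomp"])
        got = m.dynamic_coefficient("decomp", 5.0)
        assert got.value == pytest.approx(-0.182, abs=5e-4)
        assert evaluate_dynamic_coefficient([-0.151, 0.640, -0.671], 5.0) == pytest.approx(
            -0.182, abs=5e-4
        )

    def test_effect_at_landmark_zero_is_the_constant_term(self):
        m = manual_pm_model(self.PM_DECOMP, ["decomp"])
        assert m.dynamic_coefficient("decomp", 0.0).value == pytest.approx(-0.151)

    def test_age_effect_midway(self):
        assert evaluate_dynamic_coefficient([-0.009, 0.025, -0.021], 2.5) == pytest.approx(
            -0.00175, abs=1e-12
        )

    def test_ci_ordering_and_width(self):
        m = manual_pm_model(self.PM_DECOMP, ["decomp"])
        d = m.dynamic_coefficient("decomp", 2.0)
        assert d.ci_low <= d.value <= d.ci_high
        assert d.ci_high - d.ci_low == pytest.approx(2 * 1.96 * d.se)

    def test_linear_basis_effect_is_affine_in_time(self):
        params = {"Intercept": 0.0, "x": 1.0, "x:t": -0.5}
        m = manual_pm_model(params, ["x"], degree=1)
        ells = np.linspace(0, 5, 11)
        vals = np.array([m.dynamic_coefficient("x", e).value for e in ells])
        assert np.allclose(np.diff(vals, 2), 0.0, atol=1e-12)


class TestPredict:
    def test_intercept_only_pm_prediction(self):
        m = manual_pm_model({"Intercept": 2.833, "age": 0.0, "age:t": 0.0, "age:t2": 0.0}, ["age"])
        X = pd.DataFrame({"age": [57.0]})
        assert m.predict(X, 2.0)[0] == pytest.approx(2.833)

    def test_cox_zero_linear_predictor_is_baseline_conditional_survival(self):
        base = pd.Series([0.2, 0.5], index=[1.0, 3.0])
        m = lp.FittedSupermodel(
            family="cox",
            covariates=["age"],
            degree=0,
            time_scale=5.0,
            tau=3.0,
            link="log",
            params=pd.Series({"age": 0.0}),
            cov=pd.DataFrame([[1e-6]], index=["age"], columns=["age"]),
            baseline_cumhaz=base,
        )
        got = m.predict(pd.DataFrame({"age": [50.0]}), 0.0)[0]
        assert got == pytest.approx(np.exp(-0.5))

    def test_pp_prediction_clipped_and_logged(self, caplog):
        m = manual_pm_model({"Intercept": 1.2, "x": 0.0, "x:t": 0.0, "x:t2": 0.0}, ["x"])
        m.family = "PP"
        with caplog.at_level("INFO"):
            got = m.predict(pd.DataFrame({"x": [0.0]}), 1.0)[0]
        assert got == 1.0
        assert "clipped" in caplog.text

    def test_missing_covariate_rejected(self):
        m = manual_pm_model({"Intercept": 1.0, "x": 0.2, "x:t": 0.0, "x:t2": 0.0}, ["x"])
        with pytest.raises(KeyError, match="x"):
            m.predict(pd.DataFrame({"y": [1.0]}), 1.0)


@pytest.fixture(scope="module")
def cohort():
    return lp.simulate_cohort(
        lp.CohortParams(
            n_subjects=400, seed=21, censoring_hazard=0.1, baseline_hazard=0.12, admin_end=9.0
        )
    )


@pytest.fixture(scope="module")
def grid():
    return lp.make_landmark_grid(0, 5, 0.5, 3)


class TestStaticModels:
    @pytest.mark.parametrize("family", ["PM", "cox"])
    def test_model_counts_over_eleven_landmarks(self, cohort, grid, family):
        covs = ["age", "meldna"]
        sm2 = lp.fit_static_model("SM2", family, cohort, grid, covs)
        assert sm2.n_models == 1
        sm1 = lp.fit_static_model("SM1", family, cohort, grid, covs)
        sm3 = lp.fit_static_model("SM3", family, cohort, grid, covs)
        assert sm1.n_models == 11
        assert sm3.n_models == 11

    def test_static_covariates_make_sm2_sm3_coincide_at_baseline(self, cohort, grid):
        covs = ["age"]  # time-invariant: SM2 and SM3 see the same data at ell 0
        sm2 = lp.fit_static_model("SM2", "PM", cohort, grid, covs)
        sm3 = lp.fit_static_model("SM3", "PM", cohort, grid, covs)
        X = pd.DataFrame({"age": [45.0, 60.0, 75.0]})
        assert sm2.predict(X, 0.0) == pytest.approx(sm3.predict(X, 0.0), abs=1e-10)

    def test_sm3_at_baseline_equals_single_landmark_dynamic_fit(self, cohort, grid):
        covs = ["age", "meldna"]
        sm3 = lp.fit_static_model("SM3", "PM", cohort, grid, covs)
        stacked = single_landmark_stack(cohort, covs)
        with_po = lp.attach_pseudo_outcomes(stacked, 3.0, kind="mean")
        dyn0 = lp.fit_gee_supermodel(with_po, covs, tau=3.0, degree=0)
        assert sm3.models[0.0].params.to_numpy() == pytest.approx(
            dyn0.params.to_numpy(), abs=1e-8
        )

    def test_unknown_variant_rejected(self, cohort, grid):
        with pytest.raises(ValueError):
            lp.fit_static_model("SM4", "PM", cohort, grid, ["age"])


class TestTimeConstantCalibration:
    def test_interaction_terms_mostly_non_significant_under_constant_effect(self):
        """With exponential hazards the covariate effect is landmark-free, so
        the fitted time-interaction terms should pass a joint 5%-level Wald
        test (i.e. be non-significant) in at least 90% of replicates."""
        grid = lp.make_landmark_grid(0, 2, 0.5, 3)
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            cohort = lp.simulate_cohort(binary_effect_params(seed=1000 + seed, n=500))
            stacked = lp.stack_landmark_datasets(grid, cohort, covariates=["etoh"])
            with_po = lp.attach_pseudo_outcomes(stacked, 3.0, kind="mean")
            m = lp.fit_gee_supermodel(with_po, ["etoh"], tau=3.0, degree=2)
            terms = ["etoh:t", "etoh:t2"]
            beta = m.params[terms].to_numpy()
            sigma = m.cov.loc[terms, terms].to_numpy()
            wald = float(beta @ np.linalg.solve(sigma, beta))
            if stats.chi2.sf(wald, df=2) > 0.05:
                hits += 1
        assert hits >= int(np.ceil(0.9 * n_rep))


def test_coefficient_table_layout():
    m = manual_pm_model(
        {"Intercept": 2.8, "age": -0.01, "age:t": 0.02, "age:t2": -0.02}, ["age"]
    )
    tab = coefficient_table(m)
    assert list(tab.columns) == ["term", "estimate", "se", "p_value"]
    assert len(tab) == 4
    assert ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
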