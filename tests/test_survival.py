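"""Cox partial likelihood, Kaplan-Meier, log-rank and screens, checked
against hand computations, brute-force oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metabosurv as ms
from metabosurv.survival import CoxPH, SurvivalData, cox_partial_loglik


def _brute_force_loglik(time, event, X, beta):
    """Direct Breslow summation with explicit python loops."""
    ll = 0.0
    for u in sorted(set(time[event == 1])):
        deaths = np.flatnonzero((time == u) & (event == 1))
        risk = np.flatnonzero(time >= u)
        ll += sum(X[i] @ beta for i in deaths)
        ll -= len(deaths) * np.log(sum(np.exp(X[i] @ beta) for i in risk))
    return ll


def _make_data(time, event, X, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return SurvivalData(np.asarray(time, float), np.asarray(event),
                        pd.DataFrame(X, columns=names))


class TestPartialLoglik:
    def test_three_subjects_all_events_at_zero_beta(self):
        """With beta = 0 the partial likelihood is -log(3!) regardless of
        the covariates."""
        X = np.array([[5.0], [-2.0], [0.3]])
        data = _make_data([1, 2, 3], [1, 1, 1], X)
        assert cox_partial_loglik(data, [0.0]) == pytest.approx(-np.log(6), abs=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        t = rng.exponential(1, 12)
        e = rng.integers(0, 2, 12)
        e[0] = 1
        beta = np.array([0.4, -0.7])
        a = cox_partial_loglik(_make_data(t, e, X), beta)
        b = cox_partial_loglik(_make_data(t, e, X + np.array([3.0, -11.0])), beta)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_8_subject_data(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1, 8)
        e = rng.integers(0, 2, 8)
        e[rng.integers(0, 8)] = 1
        X = rng.normal(size=(8, 2))
        beta = rng.normal(size=2)
        ours = cox_partial_loglik(_make_data(t, e, X), beta)
        oracle = _brute_force_loglik(t, e, X, beta)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_requires_event(self):
        with pytest.raises(ValueError):
            _make_data([1, 2], [0, 0], np.zeros((2, 1)))


class TestCoxFit:
    def test_sign_symmetry(self, small_survival_frame):
        res = CoxPH.from_dataframe(small_survival_frame, "time_years", "event", ["x"]).fit()
        flipped = small_survival_frame.assign(x=-small_survival_frame["x"])
        res2 = CoxPH.from_dataframe(flipped, "time_years", "event", ["x"]).fit()
        assert res2.params.iloc[0] == pytest.approx(-res.params.iloc[0], abs=1e-8)
        assert abs(res2.zvalues.iloc[0]) == pytest.approx(abs(res.zvalues.iloc[0]), abs=1e-6)

    def test_centering_leaves_fit_unchanged(self, small_survival_frame):
        res = CoxPH.from_dataframe(small_survival_frame, "time_years", "event", ["x", "z"]).fit()
        shifted = small_survival_frame.assign(
            x=small_survival_frame["x"] + 100, z=small_survival_frame["z"] - 42
        )
        res2 = CoxPH.from_dataframe(shifted, "time_years", "event", ["x", "z"]).fit()
        assert np.allclose(res.params, res2.params, atol=1e-7)
        assert np.allclose(res.bse, res2.bse, atol=1e-7)
        assert np.allclose(res.pvalues, res2.pvalues, atol=1e-7)

    def test_agrees_with_lifelines(self, default_cohort):
        lifelines = pytest.importorskip("lifelines")
        cohort, _ = default_cohort
        cols = ["age_years", "phe_um", "gln_um"]
        res = CoxPH.from_dataframe(cohort, "time_years", "event", cols).fit()
        cph = lifelines.CoxPHFitter()
        cph.fit(cohort[["time_years", "event", *cols]], "time_years", "event")
        assert np.allclose(res.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(res.bse.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-6)
        assert res.llf == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_hr_and_ci_identities(self, small_survival_frame):
        res = CoxPH.from_dataframe(small_survival_frame, "time_years", "event", ["x"]).fit()
        beta, se = res.params.iloc[0], res.bse.iloc[0]
        assert res.hazard_ratios.iloc[0] == np.exp(beta)
        ci = res.conf_int()
        assert ci["ci_low"].iloc[0] == pytest.approx(np.exp(beta - 1.96 * se))
        assert ci["ci_high"].iloc[0] == pytest.approx(np.exp(beta + 1.96 * se))
        assert ci["ci_low"].iloc[0] < res.hazard_ratios.iloc[0] < ci["ci_high"].iloc[0]

    def test_constant_covariate_rejected(self, small_survival_frame):
        frame = small_survival_frame.assign(c=1.0)
        with pytest.raises(ValueError, match="constant"):
            CoxPH.from_dataframe(frame, "time_years", "event", ["c"])

    def test_duplicated_covariate_rank_deficient(self, small_survival_frame):
        frame = small_survival_frame.assign(x2=small_survival_frame["x"] * 2)
        with pytest.raises(ValueError, match="rank"):
            ms.multivariate_fit(frame, ["x", "x2"])

    def test_separation_flagged_not_raised(self):
        # covariate perfectly ordered with event times: monotone likelihood
        n = 30
        t = np.arange(1, n + 1, dtype=float)
        frame = pd.DataFrame({"time_years": t, "event": 1, "x": -t})
        res = CoxPH.from_dataframe(frame, "time_years", "event", ["x"]).fit()
        assert not res.converged
        assert res.message

    def test_newton_increases_loglik(self, small_survival_frame):
        model = CoxPH.from_dataframe(small_survival_frame, "time_years", "event", ["x", "z"])
        res = model.fit()
        assert res.llf >= res.llf_null - 1e-12


class TestUnivariateScreen:
    def test_linear_reparameterization(self, small_survival_frame):
        frame = small_survival_frame.assign(x2=small_survival_frame["x"] * 2)
        scr = ms.univariate_screen(frame, ["x", "x2"])
        row_x = scr.set_index("variable").loc["x"]
        row_x2 = scr.set_index("variable").loc["x2"]
        assert row_x2["p"] == pytest.approx(row_x["p"], abs=1e-8)
        assert row_x2["beta"] == pytest.approx(row_x["beta"] / 2, abs=1e-8)

    def test_recovers_signs_on_generated_cohort(self):
        score = ms.PolynomialScore(
            (("age_years", 1, 0.07), ("phe_um", 1, 0.06), ("gln_um", 1, -0.008))
        )
        cfg = ms.GeneratorConfig(n_patients=3000, seed=5, true_score=score, hr_per_unit=1.0)
        cohort, _ = ms.generate_cohort(cfg)
        scr = ms.univariate_screen(cohort, ["age_years", "phe_um", "gln_um"]).set_index("variable")
        assert scr.loc["age_years", "beta"] > 0
        assert scr.loc["phe_um", "beta"] > 0
        assert scr.loc["gln_um", "beta"] < 0
        assert scr["flagged"].all()

    def test_failures_recorded_not_fatal(self, small_survival_frame):
        frame = small_survival_frame.assign(c=1.0)
        scr = ms.univariate_screen(frame, ["x", "c"])
        assert scr.set_index("variable").loc["c", "error"] != ""
        assert scr.set_index("variable").loc["x", "error"] == ""

    def test_single_variable_multivariate_equals_cox_fit(self, small_survival_frame):
        multi = ms.multivariate_fit(small_survival_frame, ["x"])
        uni = CoxPH.from_dataframe(small_survival_frame, "time_years", "event", ["x"]).fit()
        assert multi.params.iloc[0] == pytest.approx(uni.params.iloc[0], abs=1e-12)


class TestKaplanMeier:
    def test_no_events_gives_flat_one(self):
        curve = ms.km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        for t in (0.5, 2.0, 10.0):
            assert curve.survival_at(t) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ms.km_estimate([], [])

    def test_hand_example(self):
        curve = ms.km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_limit_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(1, 12), 1) + 0.1
        e = rng.integers(0, 2, 12)
        e[0] = 1
        curve = ms.km_estimate(t, e)
        s = 1.0
        for u, ours in zip(curve.event_times, curve.survival):
            n_u = np.sum(t >= u)
            d_u = np.sum((t == u) & (e == 1))
            s *= 1 - d_u / n_u
            assert ours == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 40)
        curve = ms.km_estimate(t, np.ones(40, int))
        for u in t:
            assert curve.survival_at(u) == pytest.approx(np.mean(t > u), abs=1e-12)


class TestLogRank:
    def test_identical_groups_null(self):
        g = (np.array([1.0, 2, 3, 4]), np.array([1, 0, 1, 1]))
        res = ms.logrank_test([g, g])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_positive_chi2(self):
        a = (np.array([1.0, 2, 3]), np.array([1, 1, 1]))
        b = (np.array([2.0, 4, 6]), np.array([1, 1, 1]))
        res = ms.logrank_test([a, b])
        assert res.chi2 > 0

    def test_hand_worked_example(self):
        """Six subjects, O-E computed by hand: O_A=2, E_A=1.4, V=0.74."""
        a = ([1.0, 2.0, 3.0], [1, 1, 0])
        b = ([1.5, 2.5, 4.0], [1, 0, 1])
        res = ms.logrank_test([a, b])
        assert res.observed[0] == pytest.approx(2.0)
        assert res.expected[0] == pytest.approx(1.4, abs=1e-12)
        assert res.chi2 == pytest.approx(0.36 / 0.74, abs=1e-12)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        ta, tb = rng.exponential(1, 40), rng.exponential(1.6, 40)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        ea[0] = eb[0] = 1
        ours = ms.logrank_test([(ta, ea), (tb, eb)])
        ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            ms.logrank_test([(np.array([1.0]), np.array([0])), (np.array([2.0]), np.array([0]))])


class TestTertiles:
    def test_balanced_split(self):
        labels = ms.tertile_stratify(np.arange(1, 10))
        assert list(labels) == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_boundary_ties_go_low(self):
        labels = ms.tertile_stratify([1, 2, 2, 2, 3, 9])
        # q1/3 falls on the tied value 2 -> all 2s in the lower stratum
        assert all(lab == "T1" for lab, v in zip(labels, [1, 2, 2, 2, 3, 9]) if v == 2)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            ms.tertile_stratify([1.0, 1.0, 2.0])

    def test_tertile_curves_ordered_on_simulated_cohort(self):
        """Patients in the top score tertile must die fastest when the hazard
        is generated from the score itself (n = 2000)."""
        cfg = ms.GeneratorConfig(n_patients=2000, seed=8, hr_per_unit=1.0)
        cohort, record = ms.generate_cohort(cfg)
        scores = record["true_linear_predictor"]
        labels = ms.tertile_stratify(scores)
        curves = {}
        for lab in ("T1", "T2", "T3"):
            m = labels == lab
            curves[lab] = ms.km_estimate(cohort.loc[m, "time_years"], cohort.loc[m, "event"])
        at = 3.0
        assert curves["T3"].survival_at(at) < curves["T2"].survival_at(at) < curves["T1"].survival_at(at)
        for a, b in (("T1", "T2"), ("T1", "T3"), ("T2", "T3")):
            ga = (cohort.loc[labels == a, "time_years"], cohort.loc[labels == a, "event"])
            gb = (cohort.loc[labels == b, "time_years"], cohort.loc[labels == b, "event"])
            assert ms.logrank_test([ga, gb]).p_value < 0.05
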