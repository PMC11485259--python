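import numpy as np
import pandas as pd
import pytest

from lipidscore import assoc, synth
from lipidscore.scoring import ScoreDefinition


@pytest.fixture(scope="module")
def cc_table(small_cohort):
    table = synth.draw_case_cohort(small_cohort.table, 0.3, seed=11)
    table["score"] = table["true_score"]
    return table


@pytest.fixture(scope="module")
def full_cohort_table(small_cohort):
    table = small_cohort.table.copy()
    table["subcohort"] = True
    table["score"] = table["true_score"]
    return table


class TestPrenticeCox:
    def test_full_cohort_equals_standard_cox(self, full_cohort_table):
        """Oracle equivalence: subcohort == cohort reduces to standard Cox
        (independent implementation: lifelines)."""
        import lifelines
        res = assoc.fit_prentice_cox(full_cohort_table, "score", ["age", "sex", "bmi"])
        df = full_cohort_table[["score", "age", "sex", "bmi",
                                "entry_age", "exit_age", "event"]].astype(float)
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="exit_age", event_col="event", entry_col="entry_age")
        assert abs(res.log_hr - float(cph.params_["score"])) < 1e-6

    def test_case_cohort_near_truth(self, cc_table, small_gt):
        res = assoc.fit_prentice_cox(cc_table, "score", ["age", "sex", "bmi"])
        assert res.ci[0] < np.exp(small_gt.hazard_coef) < res.ci[1]

    def test_permuted_exposure_null(self, cc_table):
        df = cc_table.copy()
        rng = np.random.default_rng(3)
        df["score"] = rng.permutation(df["score"].to_numpy())
        res = assoc.fit_prentice_cox(df, "score", ["age", "sex"])
        assert abs(res.log_hr) < 3 * res.se

    def test_zero_events_rejected(self, full_cohort_table):
        df = full_cohort_table.copy()
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            assoc.fit_prentice_cox(df, "score", [])

    def test_missing_values_rejected(self, cc_table):
        df = cc_table.copy()
        df.loc[df.index[0], "score"] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            assoc.fit_prentice_cox(df, "score", [])

    def test_non_subcohort_non_case_rejected(self, cc_table):
        df = cc_table.copy()
        bad = df.index[(~df["subcohort"]) & (df["event"] == 1)][0]
        df.loc[bad, "event"] = 0
        with pytest.raises(ValueError, match="non-subcohort"):
            assoc.fit_prentice_cox(df, "score", [])

    def test_breslow_ties_supported(self, full_cohort_table):
        res = assoc.fit_prentice_cox(full_cohort_table, "score", [],
                                     ties_method="breslow")
        assert res.model["ties"] == "breslow"
        # continuous simulated times: Breslow and Efron agree closely
        efron = assoc.fit_prentice_cox(full_cohort_table, "score", [])
        assert res.log_hr == pytest.approx(efron.log_hr, abs=1e-6)

    def test_hazard_result_ci_brackets(self):
        with pytest.raises(ValueError):
            assoc.HazardResult("x", hr=0.5, ci=(0.6, 0.9), log_hr=np.log(0.5),
                               se=0.1, p=0.01, n=10, n_events=5)


class TestPercentRiskReduction:
    def test_point(self):
        hr = assoc.HazardResult("x", 0.68, (0.58, 0.79), np.log(0.68), 0.08, 1e-4, 100, 50)
        assert hr.percent_risk_reduction == pytest.approx(32.0)

    def test_null(self):
        hr = assoc.HazardResult("x", 1.0, (0.9, 1.1), 0.0, 0.05, 0.9, 100, 50)
        assert assoc.percent_risk_reduction(hr)["percent"] == pytest.approx(0.0)

    def test_ci_transform(self):
        hr = assoc.HazardResult("x", 0.5, (0.4, 0.625), np.log(0.5), 0.1, 1e-4, 100, 50)
        out = assoc.percent_risk_reduction(hr)
        assert out["percent"] == pytest.approx(50.0)
        assert out["ci"] == (pytest.approx(37.5), pytest.approx(60.0))

    def test_order_reversing(self):
        # larger HR -> smaller percent reduction (monotone-reversing transform)
        a = assoc.HazardResult("x", 0.7, (0.6, 0.8), np.log(0.7), 0.1, 0.01, 10, 5)
        b = assoc.HazardResult("x", 0.9, (0.8, 1.0), np.log(0.9), 0.1, 0.2, 10, 5)
        assert assoc.percent_risk_reduction(a)["percent"] > \
            assoc.percent_risk_reduction(b)["percent"]


def _binary_pairs(b, c, concordant=0):
    rows = []
    pid = 0
    for _ in range(b):
        rows += [dict(pair_id=pid, case=1, x=1.0), dict(pair_id=pid, case=0, x=0.0)]
        pid += 1
    for _ in range(c):
        rows += [dict(pair_id=pid, case=1, x=0.0), dict(pair_id=pid, case=0, x=1.0)]
        pid += 1
    for _ in range(concordant):
        rows += [dict(pair_id=pid, case=1, x=1.0), dict(pair_id=pid, case=0, x=1.0)]
        pid += 1
    return pd.DataFrame(rows)


def _simulate_pairs(beta, n_pairs, seed, extra_cov=False):
    """1:1 matched pairs under a conditional logistic model (exposure N(0,1))."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_pairs, 2))
    pcase = 1 / (1 + np.exp(-(beta * (x[:, 0] - x[:, 1]))))
    first_is_case = rng.random(n_pairs) < pcase
    rows = []
    for i in range(n_pairs):
        xc, xk = (x[i, 0], x[i, 1]) if first_is_case[i] else (x[i, 1], x[i, 0])
        rows += [dict(pair_id=i, case=1, x=xc), dict(pair_id=i, case=0, x=xk)]
    df = pd.DataFrame(rows)
    if extra_cov:
        df["z"] = np.random.default_rng(seed + 1).standard_normal(len(df))
    return df


class TestConditionalLogistic:
    def test_discordant_pair_closed_form(self):
        # oracle: OR = b/c over discordant pairs, exactly
        res = assoc.fit_conditional_logistic(_binary_pairs(20, 10, concordant=5),
                                             "x", standardize=False)
        assert res.odds_ratio == pytest.approx(2.0, abs=1e-9)

    def test_no_information_rejected(self):
        res_df = _binary_pairs(0, 0, concordant=10)
        with pytest.raises(ValueError, match="no information"):
            assoc.fit_conditional_logistic(res_df, "x", standardize=False)

    def test_bad_stratum_rejected(self):
        df = _binary_pairs(3, 3)
        df.loc[df.index[-1], "case"] = 1  # two cases in the last pair
        with pytest.raises(ValueError, match="1:1"):
            assoc.fit_conditional_logistic(df, "x", standardize=False)

    def test_separation_detected(self):
        with pytest.raises(ValueError, match="separation|degenerate"):
            assoc.fit_conditional_logistic(_binary_pairs(25, 0), "x", standardize=False)

    def test_recovery(self):
        beta = np.log(0.72)
        res = assoc.fit_conditional_logistic(_simulate_pairs(beta, 728, seed=5),
                                             "x", standardize=False)
        assert res.ci[0] < 0.72 < res.ci[1]

    def test_standardization_reporting(self):
        df = _simulate_pairs(np.log(0.8), 300, seed=6)
        res = assoc.fit_conditional_logistic(df, "x", standardize=True)
        assert res.model["standardized"]
        assert res.model["exposure_sd"] == pytest.approx(
            df.loc[df["case"] == 0, "x"].std(ddof=1))


class TestChangeAnalysis:
    @staticmethod
    def _pairs_with_change(seed=7, n=300, beta=-0.5):
        rng = np.random.default_rng(seed)
        t0 = rng.standard_normal((n, 2))
        delta = rng.standard_normal((n, 2))
        pdiff = delta[:, 0] - delta[:, 1]
        pcase = 1 / (1 + np.exp(-beta * pdiff))
        first_is_case = rng.random(n) < pcase
        rows = []
        for i in range(n):
            a, b = (0, 1) if first_is_case[i] else (1, 0)
            rows += [dict(pair_id=i, case=1, s0=t0[i, a], s1=t0[i, a] + delta[i, a]),
                     dict(pair_id=i, case=0, s0=t0[i, b], s1=t0[i, b] + delta[i, b])]
        return pd.DataFrame(rows)

    def test_recovery(self):
        df = self._pairs_with_change()
        res = assoc.change_analysis(df, "s0", "s1")
        # truth on the standardized-delta scale
        sd = (df.loc[df["case"] == 0, "s1"] - df.loc[df["case"] == 0, "s0"]).std(ddof=1)
        truth = np.exp(-0.5 * sd)
        assert res.ci[0] < truth < res.ci[1]

    def test_zero_change_rejected(self):
        df = self._pairs_with_change()
        df["s1"] = df["s0"]
        with pytest.raises(ValueError, match="identically zero"):
            assoc.change_analysis(df, "s0", "s1")

    def test_translation_invariance(self):
        df = self._pairs_with_change()
        res1 = assoc.change_analysis(df, "s0", "s1")
        df2 = df.copy()
        df2[["s0", "s1"]] += 5.0
        res2 = assoc.change_analysis(df2, "s0", "s1")
        assert res1.beta == pytest.approx(res2.beta, rel=1e-9)

    def test_timepoint_flag_enforced(self):
        df = self._pairs_with_change()
        df["t2_before_events"] = False
        with pytest.raises(ValueError, match="precede"):
            assoc.change_analysis(df, "s0", "s1")


class TestInteraction:
    def test_strata_sizes_differ_by_at_most_one(self):
        t = synth.simulate_effect_modified_trial(501, 0.5, 1.0, seed=8)
        res = assoc.interaction_and_strata(t)
        assert abs(res.strata_n["low"] - res.strata_n["high"]) <= 1

    def test_effect_in_low_stratum_detected(self):
        t = synth.simulate_effect_modified_trial(3000, 0.3, 1.0, seed=9,
                                                 arm_score_shift=1.5,
                                                 baseline_hazard=0.08)
        res = assoc.interaction_and_strata(t)
        assert res.p_interaction < 0.05
        assert res.strata["low"].hr < 1
        assert res.strata["low"].ci[1] < 1
        assert res.strata["high"].ci[0] < 1 < res.strata["high"].ci[1]

    def test_zero_event_stratum_flagged(self):
        t = synth.simulate_effect_modified_trial(300, 0.5, 1.0, seed=10)
        # kill all events in one arm of the high stratum
        high = t["pre_score"] > t["pre_score"].median()
        t.loc[high & (t["arm"] == 1), "event"] = 0
        res = assoc.interaction_and_strata(t)
        assert res.strata["high"] is None


class TestCorrelate:
    def test_monotone(self):
        s = pd.Series(np.arange(10.0))
        frame = pd.DataFrame({"up": np.arange(10.0) ** 2, "down": -np.arange(10.0)})
        out = assoc.correlate_score(s, frame)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_independent_small(self):
        rng = np.random.default_rng(11)
        s = pd.Series(rng.standard_normal(2000))
        frame = pd.DataFrame({"noise": rng.standard_normal(2000)})
        out = assoc.correlate_score(s, frame)
        assert abs(out.loc["noise", "rho"]) < 0.07

    def test_constant_column_missing(self):
        s = pd.Series(np.arange(5.0))
        out = assoc.correlate_score(s, pd.DataFrame({"const": np.ones(5)}))
        assert np.isnan(out.loc["const", "rho"])


def test_mutual_adjustment_attenuates_surrogate(small_cohort):
    """Joint model keeps the true driver and attenuates its noisy surrogate."""
    import lifelines
    rng = np.random.default_rng(12)
    t = small_cohort.table.copy()
    t["driver"] = t["true_score"]
    t["surrogate"] = t["true_score"] + rng.standard_normal(len(t)) * 1.0
    t["subcohort"] = True
    cph = lifelines.CoxPHFitter()
    df = t[["driver", "surrogate", "entry_age", "exit_age", "event"]].astype(float)
    cph.fit(df, duration_col="exit_age", event_col="event", entry_col="entry_age")
    joint = cph.summary
    alone = {}
    for col in ("driver", "surrogate"):
        c = lifelines.CoxPHFitter()
        c.fit(df[[col, "entry_age", "exit_age", "event"]], duration_col="exit_age",
              event_col="event", entry_col="entry_age")
        alone[col] = c.summary.loc[col, "coef"]
    atten_surr = 1 - joint.loc["surrogate", "coef"] / alone["surrogate"]
    atten_driv = 1 - joint.loc["driver", "coef"] / alone["driver"]
    assert atten_surr > atten_driv
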