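import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qtalert import alert_cohort as ac
from qtalert import outcome_models as om
from qtalert import synthetic_ehr as se


@pytest.fixture(scope="module")
def single_encounter_events():
    """One encounter per patient: exchangeable GEE must equal plain ML."""
    cfg = se.GeneratorConfig(
        n_patients=2500, seed=31,
        encounters_per_patient_dist=("fixed", {"n": 1}),
        patient_random_effect_sd=0.0,
    )
    bundle, _ = se.generate(cfg)
    events, _ = ac.build_index_events(bundle)
    return events


@pytest.fixture(scope="module")
def clustered_events():
    cfg = se.GeneratorConfig(n_patients=2500, seed=37, second_med_prob=0.05)
    bundle, _ = se.generate(cfg)
    events, _ = ac.build_index_events(bundle)
    return events


class TestSpec:
    def test_family_inference(self):
        assert om.ModelSpec("dilqts").resolved_family() == "binomial-logit"
        assert om.ModelSpec("los_days").resolved_family() == "poisson-log"

    def test_family_mismatch_rejected(self):
        with pytest.raises(ValueError):
            om.ModelSpec("dilqts", family="poisson-log").validate()
        with pytest.raises(ValueError):
            om.ModelSpec("los_days", family="binomial-logit").validate()

    def test_interaction_requires_main_effect(self):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",),
                            interactions=(("medication", "alert"),))
        with pytest.raises(ValueError):
            spec.validate()


class TestGeeEquivalence:
    def test_single_record_per_patient_matches_ml_logistic(self, single_encounter_events):
        events = single_encounter_events
        # obgyn is omitted: its rarity causes quasi-separation, where both
        # routes drift towards -inf at different stopping points
        spec = om.ModelSpec("dilqts", covariates=("age", "sex"),
                            exposures=("alert",))
        fit = om.fit_marginal(spec, events)
        assert fit.converged

        # independent oracle: Newton-Raphson ML via statsmodels Logit
        data = events[events.dilqts.notna()].reset_index(drop=True)
        X, _ = om.build_design(data, spec)
        ml = sm.Logit(data.dilqts.astype(float), X).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), ml.params.to_numpy(), atol=1e-6)

    def test_independence_structure_also_matches(self, single_encounter_events):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",),
                            correlation="independence")
        fit = om.fit_marginal(spec, single_encounter_events)
        spec2 = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",))
        fit2 = om.fit_marginal(spec2, single_encounter_events)
        assert np.allclose(fit.params.to_numpy(), fit2.params.to_numpy(), atol=1e-6)


class TestNullCase:
    def test_alert_coefficient_near_zero_under_null(self):
        cfg = se.GeneratorConfig(n_patients=6000, seed=41, alert_effect_logodds=0.0)
        bundle, _ = se.generate(cfg)
        events, _ = ac.build_index_events(bundle)
        spec = om.ModelSpec("dilqts", covariates=("age", "sex", "location"),
                            exposures=("alert",))
        fit = om.fit_marginal(spec, events)
        assert abs(fit.params["alert"]) < 3 * fit.robust_se["alert"]


class TestWald:
    def test_single_term_identity(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age", "sex"), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        stat, p, rank = om.wald_joint_test(fit, ["alert"])
        assert rank == 1
        assert stat == pytest.approx((fit.params["alert"] / fit.robust_se["alert"]) ** 2)

    def test_group_test_by_term_name(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age", "sex", "medication"),
                            exposures=("alert",),
                            interactions=(("medication", "alert"),))
        fit = om.fit_marginal(spec, clustered_events)
        stat, p, rank = om.wald_joint_test(fit, "medication:alert")
        assert rank >= 1 and 0 <= p <= 1

    def test_collinear_terms_rank_deficient(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        # duplicate a coefficient: covariance block is singular
        fit2 = om.ModelFit(
            spec=fit.spec,
            params=pd.concat([fit.params, fit.params[["alert"]].rename({"alert": "alert_dup"})]),
            robust_se=pd.concat([fit.robust_se, fit.robust_se[["alert"]].rename({"alert": "alert_dup"})]),
            pvalues=fit.pvalues, cov=None, n_obs=fit.n_obs, n_groups=fit.n_groups,
            converged=True, diagnostics=fit.diagnostics,
        )
        V = fit.cov.copy()
        V["alert_dup"] = V["alert"]
        V.loc["alert_dup"] = V.loc["alert"]
        fit2.cov = V
        stat, p, rank = om.wald_joint_test(fit2, ["alert", "alert_dup"])
        assert rank < 2

    def test_unknown_term_raises(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        with pytest.raises(ValueError):
            om.wald_joint_test(fit, ["ghost"])


class TestMargins:
    def test_intercept_only_margin_is_outcome_mean(self, single_encounter_events):
        # with independent observations the intercept-only fitted mean equals
        # the sample mean exactly (the identity is only approximate under
        # cluster-weighted exchangeable estimation)
        events = single_encounter_events
        spec = om.ModelSpec("dilqts", covariates=(), exposures=())
        fit = om.fit_marginal(spec, events)
        margin, se_ = om.predict_margins(fit, events, {})
        observed = events.dilqts.dropna().mean()
        assert margin == pytest.approx(observed, abs=1e-6)

    def test_margin_equals_bruteforce_average(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age", "sex", "location"),
                            exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        margin, _ = om.predict_margins(fit, clustered_events, {"alert_fired": 1})

        data = clustered_events[clustered_events.dilqts.notna()].copy()
        data["alert_fired"] = 1
        X, _ = om.build_design(data.reset_index(drop=True), spec, drop_constant=False)
        X = X.reindex(columns=fit.params.index, fill_value=0.0)
        probs = 1 / (1 + np.exp(-(X.to_numpy() @ fit.params.to_numpy())))
        assert margin == pytest.approx(probs.mean(), abs=1e-12)

    def test_margin_ordering_follows_coefficient_sign(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        m1, _ = om.predict_margins(fit, clustered_events, {"alert_fired": 1})
        m0, _ = om.predict_margins(fit, clustered_events, {"alert_fired": 0})
        assert (m1 > m0) == (fit.params["alert"] > 0)

    def test_unknown_condition_raises(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=(), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        with pytest.raises(ValueError):
            om.predict_margins(fit, clustered_events, {"nonexistent": 1})


class TestInvariances:
    def test_row_shuffling_invariance(self, clustered_events):
        spec = om.ModelSpec("los_days", covariates=("age", "sex"), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        shuffled = clustered_events.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = om.fit_marginal(spec, shuffled)
        assert np.allclose(
            fit.params.sort_index().to_numpy(), fit2.params.sort_index().to_numpy(), atol=1e-8
        )

    def test_deterministic_rerun(self, clustered_events):
        r1 = om.run_analysis_suite(clustered_events, suite="dilqts")
        r2 = om.run_analysis_suite(clustered_events, suite="dilqts")
        pd.testing.assert_frame_equal(r1["table"], r2["table"])

    def test_ci_definition(self, clustered_events):
        spec = om.ModelSpec("dilqts", covariates=("age",), exposures=("alert",))
        fit = om.fit_marginal(spec, clustered_events)
        ci = fit.ci95
        assert np.allclose(ci["low"], fit.params - 1.96 * fit.robust_se)
        assert np.allclose(fit.exponentiated, np.exp(fit.params))


class TestSuite:
    def test_alert_suite_structure(self, clustered_events):
        report = om.run_analysis_suite(clustered_events, suite="alert")
        assert not report["failures"]
        assert len(report["fits"]) == 8
        assert {"estimate", "exp", "p"} <= set(report["table"].columns)
        assert (report["table"].groupby("variant").size() > 0).all()

    def test_action_suite_filters_to_responded_alerts(self, clustered_events):
        report = om.run_analysis_suite(clustered_events, suite="action")
        fired = clustered_events[
            clustered_events.alert_fired
            & clustered_events.action_group.notna()
            & (clustered_events.recode_missing_reason == "none")
        ]
        n_with_outcome = fired.dilqts.notna().sum()
        assert report["fits"][0].n_obs == n_with_outcome

    def test_era_suite_carries_caveat(self, clustered_events):
        report = om.run_analysis_suite(clustered_events, suite="era")
        assert "secular-trend" in report["caveat"]

    def test_unknown_suite(self, clustered_events):
        with pytest.raises(ValueError):
            om.run_analysis_suite(clustered_events, suite="banana")


class TestCalibration:
    def test_wald_type_i_calibration(self):
        """Under a true-null coefficient group, joint Wald p-values are
        uniform (KS check over 400 simulated independent-data fits)."""
        from scipy import stats

        rng = np.random.default_rng(61)
        pvals = []
        dummy = om.ModelSpec("dilqts")
        for _ in range(400):
            n = 400
            y = (rng.uniform(size=n) < 0.3).astype(float)
            X = pd.DataFrame({"intercept": np.ones(n),
                              "x1": rng.normal(size=n),
                              "x2": rng.normal(size=n)})
            res = sm.GEE(y, X, groups=np.arange(n), family=sm.families.Binomial(),
                         cov_struct=sm.cov_struct.Independence()).fit()
            fit = om.ModelFit(
                spec=dummy,
                params=pd.Series(res.params, index=X.columns),
                robust_se=pd.Series(res.bse, index=X.columns),
                pvalues=pd.Series(res.pvalues, index=X.columns),
                cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
                n_obs=n, n_groups=n, converged=True,
            )
            _, p, _ = om.wald_joint_test(fit, ["x1", "x2"])
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_icu_alert_interaction_nominal_coverage(self):
        """With no location-by-alert effect in the generator, the robust CI
        for the ICU-alert interaction covers the null in >=93 of 100
        replicates.  Alert prevalence is raised so each replicate carries
        enough informative events; the rare obgyn stratum is excluded to
        avoid quasi-separation."""
        cover = 0
        spec = om.ModelSpec("dilqts", covariates=("age", "location"),
                            exposures=("alert",),
                            interactions=(("location", "alert"),))
        for rep in range(100):
            cfg = se.GeneratorConfig(
                n_patients=3000, seed=700 + rep,
                patient_random_effect_sd=0.0, high_qtc_prob=0.3,
            )
            bundle, _ = se.generate(cfg)
            events, _ = ac.build_index_events(bundle)
            events = events[~events.obgyn.astype(bool)].reset_index(drop=True)
            fit = om.fit_marginal(spec, events)
            lo, hi = fit.ci95.loc["icu:alert"]
            cover += bool(lo <= 0 <= hi)
        assert cover >= 93


class TestRecovery:
    def test_poisson_irr_recovery_moderate_n(self):
        cfg = se.GeneratorConfig(n_patients=8000, seed=43, alert_los_log_irr=np.log(1.5))
        bundle, truth = se.generate(cfg)
        events, _ = ac.build_index_events(bundle)
        spec = om.ModelSpec("los_days", covariates=("age", "sex", "location", "labs"),
                            exposures=("alert", "medication"))
        fit = om.fit_marginal(spec, events)
        assert fit.exponentiated["alert"] == pytest.approx(1.5, abs=0.1)

    def test_logistic_or_recovery_moderate_n(self):
        cfg = se.GeneratorConfig(n_patients=8000, seed=47,
                                 alert_effect_logodds=np.log(2.28),
                                 patient_random_effect_sd=0.0)
        bundle, truth = se.generate(cfg)
        events, _ = ac.build_index_events(bundle)
        spec = om.ModelSpec("dilqts", covariates=("age", "sex", "location"),
                            exposures=("alert", "medication"))
        fit = om.fit_marginal(spec, events)
        lo, hi = np.exp(fit.ci95.loc["alert"])
        assert lo < 2.28 < hi
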