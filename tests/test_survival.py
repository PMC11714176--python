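"""KM / log-rank / reverse-KM / Cox machinery on cohorts with known truth."""

import math

import numpy as np
import pandas as pd
import pytest

from tmescore.survival import (
    CovariateSpec,
    DegenerateModelError,
    cox_fit,
    exclude_postoperative,
    km_estimate,
    logrank_test,
    reverse_km_median_followup,
    run_model_battery,
)
from tmescore.synthetic import CohortParams, simulate_cohort


def make_recovery_params(n, log_hr, seed, covs=None):
    """Single-cause cohort for cause-specific Cox recovery tests."""
    covs = covs or {"x": {"a": 0.5, "b": 0.5}}
    return CohortParams(
        n_patients=n,
        covariates=covs,
        log_hr_dss=log_hr,
        log_hr_os={},
        baseline_shape=1.0,
        baseline_scale_cancer=10.0,
        baseline_scale_other=1e9,   # other-cause deaths switched off
        censor_range=(8.0, 20.0),
        postop_death_prob=0.0,
        seed=seed,
    )


class TestExclusion:
    def test_emulated_cohort_drops_nine(self, reference_cohort):
        filtered, n = exclude_postoperative(reference_cohort)
        assert n == 9 and len(filtered) == 162

    def test_no_flags_is_identity(self):
        df = pd.DataFrame({"postoperative_death": [False] * 5, "x": range(5)})
        filtered, n = exclude_postoperative(df)
        assert n == 0 and len(filtered) == 5

    def test_count_matches_generator_truth(self):
        coh, truth = simulate_cohort(CohortParams(seed=42, n_patients=400))
        _, n = exclude_postoperative(coh)
        assert n == truth["n_postoperative"]


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_fraction(self, rng):
        t = rng.exponential(size=60)
        est = km_estimate(t, np.ones(60))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert est.survival_at(q) == pytest.approx(np.mean(t > q), abs=1 / 60)

    def test_all_censored_stays_at_one(self):
        est = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(est.survival == 1.0)

    def test_hand_computed_five_point_example(self):
        est = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        got = est.survival_at([1, 2, 3, 4]).tolist()
        assert got == pytest.approx([0.8, 0.6, 0.6, 0.3])


class TestReverseKM:
    def test_no_deaths_gives_sample_median(self):
        times = [2.0, 5.0, 7.0, 9.0, 11.0]
        fu = reverse_km_median_followup(times, [0] * 5)
        assert fu.median_years == pytest.approx(7.0)

    def test_all_deaths_is_undefined(self):
        fu = reverse_km_median_followup([1, 2, 3], [1, 1, 1])
        assert not fu.defined

    def test_recovers_administrative_censoring_time(self):
        params = CohortParams(seed=5, n_patients=500, censor_range=(12.0, 12.0))
        coh, _ = simulate_cohort(params)
        fu = reverse_km_median_followup(coh["os_time"], coh["os_event"])
        assert fu.median_years == pytest.approx(12.0, abs=1e-9)

    def test_equals_km_with_flipped_flags(self, rng):
        t = rng.uniform(1, 10, size=80)
        e = rng.random(80) < 0.5
        fu = reverse_km_median_followup(t, e.astype(int))
        km = km_estimate(t, (1 - e).astype(int))
        assert fu.median_years == pytest.approx(
            float(km.fitter.median_survival_time_)
        )


class TestLogrank:
    def test_single_group_rejected(self):
        with pytest.raises(DegenerateModelError):
            logrank_test(["a"] * 10, np.arange(10) + 1.0, np.ones(10))

    def test_null_pvalues_uniform(self, rng):
        from scipy.stats import kstest

        t = rng.exponential(size=80)
        e = (rng.random(80) < 0.7).astype(int)
        base = np.array(["a"] * 40 + ["b"] * 40)
        ps = []
        for _ in range(500):
            ps.append(logrank_test(rng.permutation(base), t, e).p_value)
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_power_under_strong_effect(self):
        hits = 0
        for seed in range(20):
            coh, _ = simulate_cohort(
                make_recovery_params(200, {"x": {"b": math.log(3.0)}}, seed)
            )
            res = logrank_test(coh["x"], coh["dss_time"], coh["dss_event"])
            hits += res.p_value < 0.05
        assert hits >= 16  # > 80% power


class TestCox:
    def test_single_binary_hr_recovery(self):
        # mean over 3 replicate cohorts of n=2000 to damp sampling noise
        hrs = []
        for seed in (0, 1, 2):
            coh, _ = simulate_cohort(
                make_recovery_params(2000, {"x": {"b": math.log(2.0)}}, seed=seed)
            )
            fit = cox_fit(coh, [CovariateSpec("x", "a")], outcome="DSS")
            hrs.append(fit.table.loc[fit.table.level == "b", "hr"].iloc[0])
        assert 1.8 <= float(np.mean(hrs)) <= 2.2

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"dss_time": [1.0, 2, 3, 4], "dss_event": [1, 0, 1, 0],
             "x": ["a"] * 4, "postoperative_death": [False] * 4}
        )
        with pytest.raises(DegenerateModelError):
            cox_fit(df, [CovariateSpec("x", "a")], outcome="DSS")

    def test_zero_event_level_reported_not_fitted(self, rng):
        n = 90
        df = pd.DataFrame(
            {"x": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
             "dss_time": rng.uniform(1, 5, size=n)}
        )
        ev = (rng.random(n) < 0.6).astype(int)
        ev[30:60] = 0  # level b: no events
        df["dss_event"] = ev
        fit = cox_fit(df, [CovariateSpec("x", "a")], outcome="DSS")
        row = fit.table[fit.table.level == "b"].iloc[0]
        assert row["note"] == "No event" and np.isnan(row["hr"]) and row["n"] == 30
        assert fit.n == 60  # level-b subjects excluded from the likelihood

    def test_sign_agrees_with_km_ordering(self):
        coh, _ = simulate_cohort(
            make_recovery_params(600, {"x": {"b": math.log(2.5)}}, seed=3)
        )
        fit = cox_fit(coh, [CovariateSpec("x", "a")], outcome="DSS")
        hr = fit.table.loc[fit.table.level == "b", "hr"].iloc[0]
        km = {
            g: km_estimate(grp["dss_time"], grp["dss_event"])
            for g, grp in coh.groupby("x")
        }
        tq = float(np.quantile(coh["dss_time"], 0.5))
        lower_curve = "b" if km["b"].survival_at(tq) < km["a"].survival_at(tq) else "a"
        assert (hr > 1) == (lower_curve == "b")

    def test_invariant_to_level_reordering(self):
        coh, _ = simulate_cohort(
            make_recovery_params(
                500, {"x": {"b": 0.5, "c": -0.4}}, seed=9,
                covs={"x": {"a": 0.4, "b": 0.3, "c": 0.3}},
            )
        )
        f1 = cox_fit(coh, [CovariateSpec("x", "a", ("a", "b", "c"))], outcome="DSS")
        f2 = cox_fit(coh, [CovariateSpec("x", "a", ("a", "c", "b"))], outcome="DSS")
        t1 = f1.table.set_index("level")["hr"]
        t2 = f2.table.set_index("level")["hr"]
        assert t1["b"] == pytest.approx(t2["b"]) and t1["c"] == pytest.approx(t2["c"])

    def test_multivariable_ci_coverage(self):
        """95% Wald CIs cover each true log-HR in >=90% of 100 replicates."""
        truths = {"x1": math.log(2.0), "x2": math.log(1.5), "x3": 0.0,
                  "x4": -math.log(1.5)}
        covs = {k: {"a": 0.5, "b": 0.5} for k in truths}
        log_hr = {k: {"b": v} for k, v in truths.items()}
        specs = [CovariateSpec(k, "a") for k in truths]
        cover = {k: 0 for k in truths}
        n_rep = 100
        for seed in range(n_rep):
            coh, _ = simulate_cohort(
                make_recovery_params(2000, log_hr, seed=seed, covs=covs)
            )
            fit = cox_fit(coh, specs, outcome="DSS")
            t = fit.table.set_index("variable")
            for k, beta in truths.items():
                row = t.loc[k]
                row = row[row["level"] == "b"].iloc[0] if isinstance(row, pd.DataFrame) else row
                if math.log(row["ci_low"]) <= beta <= math.log(row["ci_high"]):
                    cover[k] += 1
        for k in truths:
            assert cover[k] >= 0.90 * n_rep


class TestPaperModels:
    def test_protective_clr_effect_recovered(self):
        coh, _ = simulate_cohort(CohortParams(seed=21, n_patients=800))
        coh["tnm_group"] = coh["tnm_group"].astype(str)
        filtered, _ = exclude_postoperative(coh)
        fits = run_model_battery(filtered, outcomes=("DSS",),
                                univariable=("clr",), multivariable=("clr",))
        t = fits["multi:clr:DSS"].table
        hr = t.loc[(t.variable == "clr_category") & (t.level == "low"), "hr"].iloc[0]
        assert hr > 1.0

    def test_model_covariate_lists_match_spec(self):
        coh, _ = simulate_cohort(CohortParams(seed=22, n_patients=600))
        filtered, _ = exclude_postoperative(coh)
        fits = run_model_battery(filtered, outcomes=("DSS",))
        multi = fits["multi:proximity:DSS"].table
        assert list(pd.unique(multi["variable"])) == [
            "proximity_score", "cci_group", "tnm_group",
            "necrosis_group", "stroma_group",
        ]
        uni = fits["uni:clr:DSS"].table
        assert len(uni) == 2  # low + high rows

    def test_both_outcomes_fitted(self):
        coh, _ = simulate_cohort(CohortParams(seed=23, n_patients=600))
        filtered, _ = exclude_postoperative(coh)
        fits = run_model_battery(filtered, univariable=("clr",), multivariable=("clr",))
        assert {"uni:clr:DSS", "uni:clr:OS", "multi:clr:DSS", "multi:clr:OS"} <= set(fits)
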