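"""Kaplan-Meier, log-rank, Cox fits, model comparison and concordance."""

import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from milsurv.survival import (combined_model, concordance_index, cox_fit,
                              kaplan_meier, likelihood_ratio_test,
                              logrank_test, subgroup_analysis)
from milsurv.synthetic import generate_cohort


class TestKaplanMeier:
    def test_product_limit_closed_form(self):
        km = kaplan_meier([2.0, 4.0, 6.0], [1, 0, 1])
        est = km.table.set_index("time")["estimate"]
        assert est[2.0] == pytest.approx(2 / 3)
        assert est[4.0] == pytest.approx(2 / 3)
        assert est[6.0] == pytest.approx(0.0)
        assert km.median == 6.0 and km.median_defined

    def test_no_events_flat_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km.table["estimate"] == 1.0).all()
        assert not km.median_defined and np.isnan(km.median)

    def test_doubling_records_leaves_estimate_unchanged(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        a = kaplan_meier(t, e).table
        b = kaplan_meier(np.tile(t, 2), np.tile(e, 2)).table
        assert np.allclose(a["estimate"], b["estimate"])

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        km = kaplan_meier(t, e)
        ll = KaplanMeierFitter().fit(t, e)
        ours = km.table.set_index("time")["estimate"]
        theirs = ll.survival_function_["KM_estimate"]
        for time, val in ours.items():
            assert val == pytest.approx(theirs.loc[time], abs=1e-10)

    def test_estimates_non_increasing_in_unit_interval(self, rng):
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        est = kaplan_meier(t, e).table["estimate"].to_numpy()
        assert np.all(np.diff(est) <= 1e-12)
        assert np.all((est >= 0) & (est <= 1))


class TestLogrank:
    def test_duplicated_dataset_gives_null(self, rng):
        t = rng.exponential(10, 20)
        e = np.ones(20, dtype=int)
        res = logrank_test(np.tile(t, 2), np.tile(e, 2),
                           np.repeat(["a", "b"], 20))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_toy_fixture(self):
        # A: times (1,2) both events; B: times (3,4) both events
        res = logrank_test([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                           ["A", "A", "B", "B"])
        # hand computation via hypergeometric moments: chi2 = 49/17
        assert res.statistic == pytest.approx(49 / 17, rel=1e-12)
        assert res.df == 1

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        e[:5] = 1
        g = rng.integers(0, 2, 30)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    @pytest.mark.parametrize("k_groups", [2, 3])
    def test_matches_lifelines(self, rng, k_groups):
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[:6] = 1
        g = rng.integers(0, k_groups, 60)
        res = logrank_test(t, e, g)
        ll = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_two_group_chi2_is_squared_maxstat_kernel(self, rng):
        """Cross-module consistency: the log-rank chi-square equals the
        square of the standardized statistic the cut-point search uses."""
        from milsurv._logrank import logrank_z

        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[:4] = 1
        g = rng.integers(0, 2, 40).astype(bool)
        res = logrank_test(t, e, g)
        _, _, z = logrank_z(t, e, g[None, :])
        assert res.statistic == z[0] ** 2


def _records(t, e, **cov):
    return pd.DataFrame({"time_months": t, "event": e, **cov})


class TestCoxFit:
    def test_grid_search_oracle_binary_covariate(self):
        rec = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x=[1, 0, 1, 0])
        grid = np.linspace(-5, 5, 100001)
        # 1-D Breslow/Efron partial likelihood (no ties) on the fixture
        def pll(b):
            terms = (b - np.log(2 * np.exp(b) + 2),
                     -np.log(np.exp(b) + 2),
                     b - np.log(np.exp(b) + 1))
            return sum(terms)

        best = grid[np.argmax([pll(b) for b in grid])]
        for ties in ("efron", "breslow"):
            fit = cox_fit(rec, ["x"], ties=ties)
            assert fit.coefficients["x"] == pytest.approx(best, abs=1e-3)
        assert best == pytest.approx(0.941, abs=1e-3)

    def test_breslow_matches_lifelines_without_ties(self, rng):
        n = 80
        x = rng.normal(size=n)
        z = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-0.5 * x), n) + 0.01
        e = rng.integers(0, 2, n)
        e[:8] = 1
        rec = _records(t, e, x=x, z=z)
        ours = cox_fit(rec, ["x", "z"], ties="breslow")
        theirs = cox_fit(rec, ["x", "z"], ties="efron")   # lifelines-backed
        assert np.allclose(ours.coefficients, theirs.coefficients, atol=1e-5)
        assert ours.log_likelihood == pytest.approx(theirs.log_likelihood,
                                                    rel=1e-8)
        assert np.allclose(ours.covariance, theirs.covariance, atol=1e-4)

    def test_hazard_ratio_identity_and_ci(self, rng):
        rec = _records(rng.exponential(10, 40), np.ones(40, dtype=int),
                       x=rng.normal(size=40))
        fit = cox_fit(rec, ["x"])
        s = fit.summary().iloc[0]
        b, se = fit.coefficients["x"], fit.standard_errors["x"]
        assert s["HR"] == pytest.approx(np.exp(b))
        assert s["ci_low"] == pytest.approx(np.exp(b - 1.959963984540054 * se))

    def test_constant_covariate_rejected(self):
        rec = _records([1.0, 2.0, 3.0], [1, 1, 1], x=[2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec, ["x"])

    def test_collinear_terms_named(self, rng):
        x = rng.normal(size=30)
        rec = _records(rng.exponential(10, 30), np.ones(30, dtype=int),
                       x=x, y=2 * x)
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(rec, ["x", "y"])

    def test_categorical_reference_coding(self, rng):
        n = 60
        grade = rng.choice(["1", "2", "3"], n)
        rec = _records(rng.exponential(10, n), np.ones(n, dtype=int),
                       grade=grade)
        fit = cox_fit(rec, ["grade"], categorical=["grade"])
        assert fit.terms == ["grade=2", "grade=3"]
        assert fit.term_levels["grade"] == ("1", ["1", "2", "3"])

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_separation_flagged_not_raised(self, ties):
        # perfectly separating covariate: monotone likelihood
        rec = _records([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6,
                       x=[1, 1, 1, 0, 0, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(rec, ["x"], ties=ties)
        assert fit.separation

    def test_strong_group_separation_survives_efron_fallback(self, rng):
        # two groups with disjoint event-time ranges: the Efron Newton can
        # diverge; the fit must still return with the separation flag set
        n = 60
        x = np.r_[np.ones(30), np.zeros(30)]
        t = np.r_[rng.uniform(0.1, 1, 30), rng.uniform(5, 10, 30)]
        rec = _records(t, np.ones(n, dtype=int), x=x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(rec, ["x"], ties="efron")
        assert fit.separation
        assert np.isfinite(fit.log_likelihood)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, rng):
        rec = _records(rng.exponential(10, 30), np.ones(30, dtype=int),
                       x=rng.normal(size=30))
        fit = cox_fit(rec, ["x"])
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_nested_statistic_nonnegative(self, rng):
        rec = _records(rng.exponential(10, 50), np.ones(50, dtype=int),
                       x=rng.normal(size=50), z=rng.normal(size=50))
        res = likelihood_ratio_test(cox_fit(rec, ["x"]), cox_fit(rec, ["x", "z"]))
        assert res.statistic >= 0.0 and res.df == 1

    def test_non_nested_rejected(self, rng):
        rec = _records(rng.exponential(10, 30), np.ones(30, dtype=int),
                       x=rng.normal(size=30), z=rng.normal(size=30))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(cox_fit(rec, ["z"]), cox_fit(rec, ["x"]))

    def test_different_records_rejected(self, rng):
        reca = _records(rng.exponential(10, 30), np.ones(30, dtype=int),
                        x=rng.normal(size=30))
        recb = reca.iloc[:20]
        with pytest.raises(ValueError, match="different record"):
            likelihood_ratio_test(cox_fit(reca, ["x"]),
                                  cox_fit(recb, ["x"]))


class TestConcordance:
    def test_perfectly_anti_ordered_risks(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert concordance_index([1, 2, 3, 4, 5], t, np.ones(5)) == 1.0

    def test_constant_risks_are_chance(self):
        assert concordance_index(np.zeros(6), np.arange(1.0, 7.0),
                                 np.ones(6)) == 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        r = rng.normal(size=n)
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and e[i] == 1:
                    den += 1
                    num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert concordance_index(r, t, e) == pytest.approx(num / den)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0], [1.0], [1])


def _cohort_records(seed=0, n=400):
    co = generate_cohort(n, K_true=3, d=4, bag_size_range=(2, 4),
                         clinical_effects={"node": np.log(2.0),
                                           "noise_cov": 0.0},
                         censor_rate=0.2, seed=seed)
    rec = co.survival_frame().drop(columns=["patient_id"])
    return rec


class TestCombinedModel:
    def test_screen_and_table_layout(self, rng):
        rec = _cohort_records()
        rec["ibp_group"] = np.where(rng.normal(size=len(rec)) > 0, "high", "low")
        rep = combined_model(rec, ["node", "noise_cov"],
                             categorical=["ibp_group"])
        assert "node" in rep.screened and "noise_cov" not in rep.screened
        # one reference row ("low") plus one HR row per non-reference level
        ibp_rows = rep.table[rep.table["variable"] == "ibp_group"]
        assert len(ibp_rows) == 2
        assert ibp_rows["HR"].isna().sum() == 1
        assert rep.lrt.df == 1

    def test_informative_ibp_gives_small_lrt_p(self):
        rec = _cohort_records(seed=1)
        # IBP group correlated with outcome (noisy median split of time)
        rng = np.random.default_rng(1)
        eta_rank = rec["time_months"].rank() + rng.normal(0, 80, len(rec))
        rec["ibp_group"] = np.where(eta_rank > np.median(eta_rank), "high", "low")
        rep = combined_model(rec, ["node"], categorical=["ibp_group"])
        assert rep.lrt.p_value < 0.01


class TestSubgroups:
    def test_single_stratum_equals_unstratified(self, rng):
        rec = _cohort_records(seed=2, n=120)
        rec["ibp_group"] = np.where(rng.normal(size=len(rec)) > 0, "high", "low")
        rec["stratum"] = "all"
        out = subgroup_analysis(rec, "stratum")
        fit = cox_fit(rec, ["ibp_group"], categorical=["ibp_group"])
        assert len(out) == 1
        assert out["HR"].iloc[0] == pytest.approx(
            fit.summary()["HR"].iloc[0])

    def test_eventless_stratum_skipped_with_warning(self, rng):
        rec = _cohort_records(seed=3, n=60)
        rec["ibp_group"] = np.where(rng.normal(size=len(rec)) > 0, "high", "low")
        rec["adjuvant"] = np.where(np.arange(len(rec)) < 10, "none", "gem")
        rec.loc[rec["adjuvant"] == "none", "event"] = 0
        with pytest.warns(UserWarning, match="no events"):
            out = subgroup_analysis(rec, "adjuvant")
        assert out["stratum"].tolist() == ["gem"]
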