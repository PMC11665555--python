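"""Survival engines: KM, log-rank, Cox, median split, cutpoint scan."""

import numpy as np
import pandas as pd
import pytest

import resistomics as rx
from resistomics import survival as sv
from resistomics.simulate import SimulationSpec, gen_survival_cohort


def cohort_df(time, event, expression=None) -> pd.DataFrame:
    n = len(time)
    return pd.DataFrame({
        "subject": [f"S{i}" for i in range(n)],
        "time": time,
        "event": event,
        "expression": expression if expression is not None else np.zeros(n),
    })


class TestKaplanMeier:
    def test_single_event_product_limit(self):
        km = sv.km_estimate(np.array([1.0, 2, 3, 4]),
                            np.array([True, False, False, False]))
        assert sv.km_survival_at(km, 1.0) == pytest.approx(3 / 4)
        assert km.iloc[0]["at_risk"] == 4

    def test_zero_events_flat_at_one(self):
        km = sv.km_estimate(np.array([1.0, 2, 3]), np.zeros(3, dtype=bool))
        assert len(km) == 0
        assert sv.km_survival_at(km, 99.0) == 1.0

    def test_curve_non_increasing_from_one(self, rng):
        t = rng.exponential(5, size=80)
        e = rng.random(80) < 0.7
        km = sv.km_estimate(t, e)
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-15).all() and s[0] <= 1.0

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(3, size=150)
        km = sv.km_estimate(t, np.ones(150, dtype=bool))
        for row in km.itertuples():
            empirical = (t > row.time).mean()
            assert row.survival == pytest.approx(empirical, abs=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            sv.km_estimate(np.array([0.0, 1.0]), np.array([True, True]))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        mask = np.array([True] * 4 + [False] * 4)
        stat, p = sv.logrank_test(t, e, mask)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_to_group_relabeling(self, rng):
        t = rng.exponential(5, size=60)
        e = rng.random(60) < 0.8
        mask = rng.random(60) < 0.5
        s1, p1 = sv.logrank_test(t, e, mask)
        s2, p2 = sv.logrank_test(t, e, ~mask)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test(np.array([1.0, 2]), np.array([True, True]),
                            np.array([True, True]))

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        t = np.ceil(rng.exponential(4, size=120))  # heavy ties
        e = rng.random(120) < 0.7
        mask = rng.random(120) < 0.5
        stat, p = sv.logrank_test(t, e, mask)
        ref = ll_logrank(t[mask], t[~mask], e[mask], e[~mask])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCox:
    def test_matches_reference_implementations(self, rng):
        """Coefficient and SE agree with statsmodels PHReg (Efron ties)
        to near machine precision, and with lifelines at its tightest
        convergence setting."""
        import lifelines
        import statsmodels.api as sm
        for i in range(5):
            n = 150
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x))
            t = np.ceil(t * 10) / 10  # induce ties to exercise Efron
            e = rng.random(n) < 0.8
            mine = sv.cox_univariate(t, e, x)
            ref = sm.PHReg(t, x[:, None], status=e.astype(int),
                           ties="efron").fit()
            assert mine.coef == pytest.approx(float(ref.params[0]), abs=1e-9)
            assert mine.se == pytest.approx(
                float(np.sqrt(ref.cov_params()[0, 0])), abs=1e-9)
            if i == 0:
                cph = lifelines.CoxPHFitter()
                cph.fit(pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E",
                        fit_options={"precision": 1e-12})
                assert mine.coef == pytest.approx(
                    float(cph.params_.iloc[0]), abs=1e-9)

    def test_binary_label_swap_gives_reciprocal_hr(self, rng):
        n = 100
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-x))
        e = np.ones(n, dtype=bool)
        r1 = sv.cox_univariate(t, e, x)
        r2 = sv.cox_univariate(t, e, 1 - x)
        assert r1.hr == pytest.approx(1 / r2.hr, rel=1e-6)
        assert r1.ci_low == pytest.approx(1 / r2.ci_high, rel=1e-6)
        assert r1.ci_high == pytest.approx(1 / r2.ci_low, rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sv.cox_univariate(np.array([1.0, 2, 3, 4]),
                              np.array([1, 1, 0, 1], dtype=bool),
                              np.ones(4))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            sv.cox_univariate(np.array([1.0, 2]), np.zeros(2, dtype=bool),
                              np.array([0.0, 1.0]))

    def test_complete_separation_flagged_not_estimated(self):
        """All events in the high group and all censoring in the low
        group: the partial likelihood is monotone and must be flagged."""
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        r = sv.cox_univariate(t, e, x)
        assert not r.converged
        assert np.isnan(r.hr)

    def test_ci_brackets_hazard_ratio(self, rng):
        coh, _ = gen_survival_cohort(SimulationSpec(seed=4, n_subjects=300))
        r = sv.cox_univariate(coh["time"].values,
                              coh["event"].values.astype(bool),
                              coh["expression"].values)
        assert r.ci_low <= r.hr <= r.ci_high


class TestMedianSplit:
    def test_even_cohort_splits_in_half(self):
        expr = np.arange(1.0, 11.0)
        t = np.linspace(1, 10, 10)
        e = np.ones(10, dtype=bool)
        res = sv.median_split(cohort_df(t, e.astype(int), expr))
        assert res.high_mask.sum() == 5
        assert set(expr[res.high_mask]) == {6.0, 7, 8, 9, 10}

    def test_replicating_every_subject_preserves_hr(self):
        """Duplicating every subject leaves the split and (nearly) the HR
        unchanged: exact invariance holds under Breslow ties, while the
        Efron correction used here sees the duplication-induced ties and
        shifts the estimate marginally."""
        coh, _ = gen_survival_cohort(SimulationSpec(seed=8, n_subjects=101))
        res1 = sv.median_split(coh)
        doubled = pd.concat([coh, coh], ignore_index=True)
        res2 = sv.median_split(doubled)
        assert np.array_equal(res2.high_mask,
                              np.concatenate([res1.high_mask] * 2))
        assert res2.cox.hr == pytest.approx(res1.cox.hr, rel=0.02)

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            sv.median_split(cohort_df(np.arange(1.0, 5), np.ones(4, int),
                                      np.ones(4)))

    def test_null_hr_ci_covers_one(self):
        """With no expression effect the 95% CI contains HR = 1 in at
        least 90 of 100 seeds."""
        cover = 0
        for seed in range(100):
            coh, _ = gen_survival_cohort(
                SimulationSpec(seed=seed, true_log_hr=0.0, n_subjects=150))
            res = sv.median_split(coh)
            cover += res.cox.ci_low <= 1.0 <= res.cox.ci_high
        assert cover >= 90


class TestCutpointScan:
    def test_median_cutoff_reproduces_median_split(self):
        for n in (101, 100):  # odd and even cohorts
            coh, _ = gen_survival_cohort(
                SimulationSpec(seed=21, n_subjects=n))
            ms = sv.median_split(coh)
            scan = sv.cutpoint_scan(coh, rx.AnalysisConfig(n_cutoffs=41))
            expr = coh["expression"].to_numpy()
            med_cut = float(np.quantile(expr, 0.5, method="higher"))
            row = scan.table.loc[scan.table["cutoff"] == med_cut]
            assert len(row) == 1
            assert row.iloc[0]["hr"] == ms.cox.hr
            assert row.iloc[0]["logrank_p"] == ms.logrank_p

    def test_sign_flip_mirrors_scan(self):
        """Negating expression maps each cutoff's split to the complement
        of the split one distinct value below, so HRs are reciprocal."""
        coh, _ = gen_survival_cohort(SimulationSpec(seed=31, n_subjects=80))
        cfg = rx.AnalysisConfig(n_cutoffs=None,
                                cutoff_grid_quantiles=(0.2, 0.8))
        fwd = sv.cutpoint_scan(coh, cfg)
        neg = coh.copy()
        neg["expression"] = -neg["expression"]
        rev = sv.cutpoint_scan(neg, cfg)
        vals = np.sort(coh["expression"].unique())
        rev_by_cut = {round(c, 12): h for c, h in
                      zip(rev.table["cutoff"], rev.table["hr"])}
        checked = 0
        for row in fwd.table.itertuples():
            i = np.searchsorted(vals, row.cutoff)
            if i == 0:
                continue
            prev = vals[i - 1]
            key = round(-prev, 12)
            if key in rev_by_cut:
                assert rev_by_cut[key] == pytest.approx(1 / row.hr, rel=1e-6)
                checked += 1
        assert checked >= 10

    def test_chosen_rule_min_p(self):
        coh, _ = gen_survival_cohort(
            SimulationSpec(seed=41, hazard_model="threshold",
                           n_subjects=400))
        scan = sv.cutpoint_scan(coh, rx.AnalysisConfig())
        valid = scan.table[scan.table["converged"]]
        assert scan.chosen_cutoff in set(
            valid.loc[valid["logrank_p"] == valid["logrank_p"].min(),
                      "cutoff"])
        assert "selection" in scan.notes["selection_bias"]

    def test_too_few_subjects_rejected(self):
        coh = cohort_df(np.arange(1.0, 6), np.ones(5, int), np.arange(5.0))
        with pytest.raises(ValueError, match="10 subjects"):
            sv.cutpoint_scan(coh, rx.AnalysisConfig())

    def test_min_p_selection_inflates_null_rejections(self):
        """Scanning many cutoffs and keeping the smallest p rejects a
        true null far more often than the nominal 5% level."""
        rej = 0
        for seed in range(60):
            coh, _ = gen_survival_cohort(
                SimulationSpec(seed=seed, true_log_hr=0.0, n_subjects=120))
            scan = sv.cutpoint_scan(coh, rx.AnalysisConfig())
            valid = scan.table[scan.table["converged"]]
            rej += valid["logrank_p"].min() < 0.05
        assert rej / 60 > 0.05
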