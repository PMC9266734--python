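"""Survival screen: dichotomization, KM, log-rank, Cox (Breslow ties)."""

import numpy as np
import pandas as pd
import pytest

from penmark.datatypes import AnalysisConfig, ExpressionMatrix
from penmark.errors import InsufficientDataError
from penmark.pipeline import quantify
from penmark.simulate import SimulationConfig, simulate_cohort
from penmark.surv import (
    cox_ph_fit,
    dichotomize_by_median,
    kaplan_meier,
    logrank_test,
    survival_marker_screen,
)

from oracles import km_no_censoring


class TestDichotomize:
    def test_even_split(self):
        labels, deg = dichotomize_by_median(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        )
        assert not deg
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_median_sample_goes_low(self):
        labels, deg = dichotomize_by_median(
            pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        )
        assert labels["b"] == "low"  # the median itself
        assert set(labels[labels == "high"].index) == {"c"}

    def test_all_identical_is_degenerate(self):
        _, deg = dichotomize_by_median(pd.Series([2.0] * 5))
        assert deg

    def test_order_invariance_and_low_count(self, rng):
        v = pd.Series(rng.normal(size=11), index=[f"s{i}" for i in range(11)])
        labels, _ = dichotomize_by_median(v)
        perm = v.sample(frac=1.0, random_state=1)
        labels2, _ = dichotomize_by_median(perm)
        assert (labels.sort_index() == labels2.sort_index()).all()
        assert (labels == "low").sum() == 6  # ceil(11/2) at odd n


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert len(km.times) == 0
        assert km.survival_at(99.0) == 1.0

    def test_hand_worked_product_limit(self):
        # events at 1 and 3, censored at 2: S = 2/3 on [1,3), then 0
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_single_subject_event(self):
        km = kaplan_meier([5.0], [1])
        assert km.survival_at(4.9) == 1.0 and km.survival_at(5.0) == 0.0

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, size=40)
        km = kaplan_meier(t, np.ones(40, dtype=int))
        for u, s in km_no_censoring(t).items():
            assert km.survival_at(u) == pytest.approx(s, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = np.round(rng.exponential(10, size=30), 0) + 1
        e = rng.integers(0, 2, 30)
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in km.times:
            assert km.survival_at(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
            )

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientDataError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        r = logrank_test(t, e, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_no_events_flagged(self):
        r = logrank_test([1.0, 2.0], [0, 0], [0, 1])
        assert r.degenerate and r.p_value == 1.0

    def test_matches_lifelines_worked_instance(self):
        from lifelines.statistics import logrank_test as ll

        t = np.array([3.0, 5, 7, 2, 18, 6, 9, 11, 14, 1.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        g = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        mine = logrank_test(t, e, g)
        ref = ll(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_equals_cox_score_test_without_ties(self, rng):
        # classical identity: log-rank == Cox score chi-square at beta=0
        from penmark.surv import _cox_loglik_grad_hess

        for _ in range(10):
            n = 30
            t = rng.exponential(10, size=n)  # continuous, no ties
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            order = np.argsort(-t)
            _, grad, hess = _cox_loglik_grad_hess(
                np.zeros(1), t[order], e[order], g[order].astype(float)[:, None]
            )
            score_chi2 = grad[0] ** 2 / -hess[0, 0]
            assert logrank_test(t, e, g).statistic == pytest.approx(
                score_chi2, rel=1e-10
            )


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        n = 4000
        x = rng.normal(size=n)
        t = rng.exponential(10, size=n)
        e = np.ones(n, dtype=int)
        fit = cox_ph_fit(t, e, x[:, None])
        lo, hi = fit.ci()
        assert lo[0] < 1.0 < hi[0]

    def test_planted_beta_recovered(self, rng):
        hrs = []
        for _ in range(20):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
            fit = cox_ph_fit(t, np.ones(n, dtype=int), x[:, None])
            hrs.append(fit.hr[0])
        assert 1.8 <= np.median(hrs) <= 2.2

    def test_monotone_likelihood_flag(self):
        # binary covariate with zero events in one stratum
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = e.astype(float)[:, None]  # events only where x=1
        fit = cox_ph_fit(t, e, x)
        assert fit.convergence == "monotone_likelihood"
        assert abs(fit.beta[0]) > 10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph_fit([1.0, 2.0, 3.0], [1, 1, 0], np.ones((3, 1)))

    def test_no_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            cox_ph_fit([1.0, 2.0], [0, 0], np.array([[0.0], [1.0]]))

    def test_matches_scikit_survival_with_ties(self, rng):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        for _ in range(5):
            n = 40
            X = rng.normal(size=(n, 2))
            t = np.ceil(rng.exponential(10 / np.exp(0.5 * X[:, 0]), size=n))
            e = rng.random(n) < 0.7
            if e.sum() < 3:
                continue
            fit = cox_ph_fit(t, e.astype(int), X, tol=1e-12)
            y = np.array(list(zip(e, t)), dtype=[("e", "?"), ("t", "f8")])
            ref = CoxPHSurvivalAnalysis(tol=1e-12, n_iter=200).fit(X, y)
            assert np.abs(fit.beta - ref.coef_).max() < 1e-8


@pytest.fixture(scope="module")
def survival_cohort():
    cfg = SimulationConfig(
        n_per_group=60, n_mirnas=2, n_genes=5, n_endogenous_mrna=3,
        n_endogenous_mirna=2,
        survival_betas={"BAX": 2.5}, censor_rate=0.3, seed=77,
    )
    ct, ann, truth = simulate_cohort(cfg)
    mrna, _, _, _ = quantify(ct, ann, AnalysisConfig())
    return mrna, ann


class TestMarkerScreen:

    def test_planted_marker_significant(self, survival_cohort):
        mrna, ann = survival_cohort
        res = {r.marker: r for r in survival_marker_screen(mrna, ann, "os")}
        assert res["BAX"].logrank_p < 0.05
        assert res["BAX"].hr > 1.0
        assert res["BAX"].ci_low > 1.0

    def test_css_default_adjustment_recorded(self, survival_cohort):
        mrna, ann = survival_cohort
        res = survival_marker_screen(mrna, ann, "css")
        assert res[0].adjusted_for == (
            "lymph_node_metastasis", "perineural_invasion"
        )
        res_os = survival_marker_screen(mrna, ann, "os")
        assert res_os[0].adjusted_for == ()

    def test_noise_adjusters_do_not_move_estimate(self, survival_cohort):
        mrna, ann = survival_cohort
        ann.data["noise_cov"] = np.random.default_rng(5).integers(
            0, 2, len(ann.samples)
        )
        plain = {r.marker: r for r in survival_marker_screen(mrna, ann, "os", [])}
        adj = {
            r.marker: r
            for r in survival_marker_screen(mrna, ann, "os", ["noise_cov"])
        }
        assert np.log(adj["BAX"].hr) == pytest.approx(
            np.log(plain["BAX"].hr), abs=0.3
        )

    def test_degenerate_marker_skipped_with_reason(self, survival_cohort):
        mrna, ann = survival_cohort
        vals = mrna.values.copy()
        vals["FLAT"] = 1.0
        expr = ExpressionMatrix(vals, mrna.normalization_refs)
        res = {r.marker: r for r in survival_marker_screen(expr, ann, "os")}
        assert res["FLAT"].skipped
        assert "degenerate" in res["FLAT"].reason
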