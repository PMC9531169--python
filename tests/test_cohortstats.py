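"""Survival model fits vs closed forms, grid-search and lifelines oracles."""

import numpy as np
import pandas as pd
import pytest

from fetpet import (
    SurvivalCohort,
    fit_coxph,
    fit_loglogistic,
    make_survival_cohort,
    median_split,
    scan_cutoffs,
    univariate_table,
)
from fetpet.cohortstats import ConvergenceError, km_curve, loglogistic_survival


def grid_search_loglogistic(time, event, alphas, betas):
    """Independent brute-force MLE over an (alpha, beta) grid."""
    t = time[:, None, None]
    e = event[:, None, None]
    a = alphas[None, :, None]
    b = betas[None, None, :]
    z = (t / a) ** b
    logS = -np.log1p(z)
    logf = np.log(b) - np.log(a) + (b - 1) * (np.log(t) - np.log(a)) + 2 * logS
    ll = np.where(e, logf, logS).sum(axis=0)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(alphas[i]), float(betas[j])


class TestLogLogistic:
    def test_large_sample_recovery(self):
        coh = make_survival_cohort(10_000, 3.0, 0.0, shape=2.0, scale_base=12.0,
                                   censor_rate=0.0, seed=5)
        fit = fit_loglogistic(coh)
        assert 11.6 <= fit.alpha_ <= 12.4
        assert 1.9 <= fit.shape_ <= 2.1

    def test_matches_grid_search_oracle_at_n50(self):
        coh = make_survival_cohort(50, 3.0, 0.0, censor_rate=0.2, seed=6)
        fit = fit_loglogistic(coh)
        alphas = np.linspace(5.0, 25.0, 401)   # step 0.05
        betas = np.linspace(0.5, 4.0, 351)     # step 0.01
        a_hat, b_hat = grid_search_loglogistic(coh.time, coh.event, alphas, betas)
        assert fit.alpha_ == pytest.approx(a_hat, abs=0.05)
        assert fit.shape_ == pytest.approx(b_hat, abs=0.01)

    def test_matches_lifelines_with_covariate(self):
        lifelines = pytest.importorskip("lifelines")
        coh = make_survival_cohort(300, 3.0, 0.8, seed=7)
        sub = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                             pd.DataFrame({"high": (coh.suvmax > 3.0).astype(float)}))
        fit = fit_loglogistic(sub, ["high"])
        df = pd.DataFrame({"T": coh.time, "E": coh.event.astype(int),
                           "high": (coh.suvmax > 3.0).astype(float)})
        ll = lifelines.LogLogisticAFTFitter().fit(df, "T", "E")
        assert fit.coef("high") == pytest.approx(
            ll.params_[("alpha_", "high")], abs=1e-4)
        assert fit.p("high") == pytest.approx(
            ll.summary.loc[("alpha_", "high"), "p"], rel=0.05)

    def test_survival_identity_at_alpha(self):
        # S(alpha) = 1/2 for every shape
        assert loglogistic_survival(12.0, 12.0, 2.7) == pytest.approx(0.5)

    def test_null_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            coh = make_survival_cohort(80, 3.0, 0.0, seed=20_000 + s)
            sub = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                                 pd.DataFrame({"high": (coh.suvmax > 3.0).astype(float)}))
            rejections += fit_loglogistic(sub, ["high"]).p("high") < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_degenerate_inputs_rejected(self):
        coh = make_survival_cohort(50, 3.0, 0.5, seed=8)
        none = SurvivalCohort(coh.time, np.zeros(50, bool), coh.suvmax)
        with pytest.raises(ValueError, match="events"):
            fit_loglogistic(none)
        const = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                               pd.DataFrame({"c": np.ones(50)}))
        with pytest.raises(ValueError, match="'c'"):
            fit_loglogistic(const, ["c"])


class TestCox:
    def test_three_subject_closed_form(self):
        # event times 1 < 2 < 3, x = (1, 0, 1): beta-hat = -(1/2) ln 2
        coh = SurvivalCohort([1.0, 2.0, 3.0], [1, 1, 1], [0, 0, 0],
                             pd.DataFrame({"x": [1.0, 0.0, 1.0]}))
        fit = fit_coxph(coh, ["x"])
        assert fit.coef("x") == pytest.approx(-0.5 * np.log(2.0), abs=1e-4)

    def test_two_group_exponential_hr_recovery(self):
        rng = np.random.default_rng(9)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        coh = SurvivalCohort(t, np.ones(n, bool), x, pd.DataFrame({"x": x}))
        fit = fit_coxph(coh, ["x"])
        assert 0.62 <= fit.coef("x") <= 0.77

    def test_matches_lifelines_on_tie_free_data(self):
        lifelines = pytest.importorskip("lifelines")
        coh = make_survival_cohort(200, 3.0, 0.6, seed=10)
        sub = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                             pd.DataFrame({"suv": coh.suvmax}))
        fit = fit_coxph(sub, ["suv"])
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": coh.time, "E": coh.event.astype(int), "suv": coh.suvmax}),
            "T", "E")
        # Efron == Breslow when event times are continuous (no ties)
        assert fit.coef("suv") == pytest.approx(cph.params_["suv"], abs=1e-5)

    def test_constant_covariate_rejected(self):
        coh = SurvivalCohort([1, 2, 3, 4], [1, 1, 1, 0], [1, 2, 3, 4],
                             pd.DataFrame({"z": [0.0] * 4}))
        with pytest.raises(ValueError, match="'z'"):
            fit_coxph(coh, ["z"])

    def test_perfect_separation_raises(self):
        # covariate perfectly ordered with event times -> monotone likelihood
        t = np.arange(1.0, 41.0)
        x = np.arange(40.0)
        coh = SurvivalCohort(t, np.ones(40, bool), x, pd.DataFrame({"x": x}))
        with pytest.raises(ConvergenceError, match="penaliz"):
            fit_coxph(coh, ["x"])


class TestMedianSplit:
    def test_even_n(self):
        coh = SurvivalCohort([1, 2, 3, 4], [1] * 4, [1.0, 2.0, 3.0, 4.0])
        cutoff, high = median_split(coh)
        assert cutoff == 2.5
        assert high.sum() == 2

    def test_strict_greater_sends_median_to_low_group(self):
        coh = SurvivalCohort([1, 2, 3, 4, 5], [1] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        cutoff, high = median_split(coh)
        assert cutoff == 3.0
        assert not high[2]  # subject at the median is 'low'

    def test_constant_suvmax_rejected(self):
        coh = SurvivalCohort([1, 2, 3, 4], [1] * 4, [2.0] * 4)
        with pytest.raises(ValueError, match="constant"):
            median_split(coh)


class TestScanCutoffs:
    def test_recovery_is_close_in_median(self):
        # median |optimal - truth| bound frozen from a 100-replicate
        # simulation of the same generator (median ~0.11)
        devs = []
        for s in range(20):
            coh = make_survival_cohort(120, 3.0, 0.8, seed=30_000 + s)
            devs.append(abs(scan_cutoffs(coh).optimal_cutoff - 3.0))
        assert np.median(devs) <= 0.3

    def test_optimal_p_not_larger_than_median_split_p(self):
        coh = make_survival_cohort(120, 3.0, 0.8, seed=11)
        scan = scan_cutoffs(coh)
        med, high = median_split(coh)
        sub = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                             pd.DataFrame({"high": high.astype(float)}))
        p_med = fit_loglogistic(sub, ["high"]).p("high")
        assert scan.optimal_p <= p_med

    def test_trace_is_complete_and_optimum_in_grid(self):
        coh = make_survival_cohort(60, 3.0, 0.8, seed=12)
        scan = scan_cutoffs(coh, min_group=5)
        assert len(scan.trace) == len(scan.grid)
        assert scan.optimal_cutoff in scan.grid
        assert ((coh.suvmax > scan.grid[:, None]).sum(axis=1) >= 5).all()

    def test_min_group_too_large_rejected(self):
        coh = make_survival_cohort(10, 3.0, 0.5, seed=13)
        with pytest.raises(ValueError):
            scan_cutoffs(coh, min_group=6)

    def test_cox_model_variant_runs(self):
        coh = make_survival_cohort(60, 3.0, 0.8, seed=14)
        scan = scan_cutoffs(coh, model="cox_ph", min_group=8)
        assert np.isfinite(scan.optimal_p)


class TestUnivariateTable:
    def test_planted_strong_covariate_selected_alone(self):
        rng = np.random.default_rng(15)
        coh0 = make_survival_cohort(150, 3.0, 1.2, seed=15)
        cov = pd.DataFrame({
            "high_suv": (coh0.suvmax > 3.0).astype(float),
            "noise": rng.normal(size=150),
        })
        coh = SurvivalCohort(coh0.time, coh0.event, coh0.suvmax, cov)
        table, selected = univariate_table(coh, ["high_suv", "noise"], alpha=0.05)
        assert "high_suv" in selected
        assert "noise" not in selected

    def test_alpha_one_selects_every_fitable(self):
        coh0 = make_survival_cohort(80, 3.0, 0.5, seed=16)
        cov = pd.DataFrame({"a": np.random.default_rng(1).normal(size=80)})
        coh = SurvivalCohort(coh0.time, coh0.event, coh0.suvmax, cov)
        _, selected = univariate_table(coh, ["a"], alpha=1.0)
        assert selected == ["a"]

    def test_constant_candidate_marked_failed_others_intact(self):
        coh0 = make_survival_cohort(80, 3.0, 1.0, seed=17)
        cov = pd.DataFrame({"c": np.ones(80),
                            "high": (coh0.suvmax > 3.0).astype(float)})
        coh = SurvivalCohort(coh0.time, coh0.event, coh0.suvmax, cov)
        table, selected = univariate_table(coh, ["c", "high"])
        row = table.set_index("covariate").loc["c"]
        assert row["status"].startswith("failed")
        assert "high" in selected


def test_km_curve_simple_product_limit():
    df = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
    # S(1) = 2/3; censoring at 2; S(3) = 2/3 * (1 - 1/1) = 0
    assert df["survival"].tolist() == pytest.approx([1.0, 2 / 3, 0.0])


def test_censoring_widens_standard_errors_on_average():
    ses = {}
    for cr in (0.0, 0.5):
        acc = []
        for s in range(20):
            coh = make_survival_cohort(100, 3.0, 0.5, censor_rate=cr, seed=40_000 + s)
            sub = SurvivalCohort(coh.time, coh.event, coh.suvmax,
                                 pd.DataFrame({"high": (coh.suvmax > 3.0).astype(float)}))
            acc.append(fit_loglogistic(sub, ["high"]).params.loc["high", "se"])
        ses[cr] = np.mean(acc)
    assert ses[0.5] > ses[0.0]
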