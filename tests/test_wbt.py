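"""MAD filtering, grade-adjusted gene association, multiplicity, mixed models."""

import numpy as np
import pandas as pd
import pytest

from fetpet import (
    ExpressionStudy,
    associate_genes,
    mad_filter,
    make_expression_study,
    mixed_checkpoint_model,
)
from fetpet.wbt import gene_mad


def small_study(expr: np.ndarray, suv, grade=None, patient=None, tp=None) -> ExpressionStudy:
    n = expr.shape[1]
    samples = pd.DataFrame({
        "suvmax": suv,
        "initial_grade": grade if grade is not None else [3] * (n // 2) + [4] * (n - n // 2),
        "patient_id": patient if patient is not None else [f"P{i}" for i in range(n)],
        "timepoint": tp if tp is not None else [0] * n,
    }, index=[f"S{i}" for i in range(n)])
    genes = [f"G{i}" for i in range(expr.shape[0])]
    return ExpressionStudy(pd.DataFrame(expr, index=genes, columns=samples.index), samples)


class TestMadFilter:
    def test_mad_of_one_to_five_is_one(self):
        expr = np.vstack([[1, 2, 3, 4, 5], [0, 0, 0, 0, 0]]).astype(float)
        st = small_study(expr, suv=[1, 2, 3, 4, 5])
        assert gene_mad(st.expr)["G0"] == 1.0

    def test_top_fraction_count_and_constant_never_kept(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(10, 6))
        expr[3] = 7.0  # constant gene: MAD 0
        st = small_study(expr, suv=rng.uniform(1, 5, 6))
        kept = mad_filter(st, 0.1)
        assert kept.n_genes == 1
        assert "G3" not in kept.expr.index

    def test_invariance_to_shift_and_global_scale(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(20, 8))
        st = small_study(expr, suv=rng.uniform(1, 5, 8))
        shifted = small_study(expr + rng.normal(size=(20, 1)), suv=st.samples["suvmax"])
        scaled = small_study(expr * 3.7, suv=st.samples["suvmax"])
        base = list(mad_filter(st, 0.25).expr.index)
        assert list(mad_filter(shifted, 0.25).expr.index) == base
        assert list(mad_filter(scaled, 0.25).expr.index) == base

    def test_bad_fraction_rejected(self):
        st = small_study(np.ones((2, 4)) + np.arange(4), suv=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            mad_filter(st, 0.0)


class TestAssociateGenes:
    def test_planted_gene_survives_bonferroni(self):
        st = make_expression_study(50, 9, 3, beta=2.0, grade_confounding=0.5,
                                   seed=2, residual_sd=0.1, patient_sd=0.0)
        tab = associate_genes(st)
        assert (tab.loc[st.planted_genes, "p"] < 0.001).all()
        assert (tab.loc[st.planted_genes, "p_bonferroni"] < 0.05).all()

    def test_matches_statsmodels_single_gene(self):
        import statsmodels.api as sm
        st = make_expression_study(5, 15, 1, beta=1.0, grade_confounding=0.4, seed=3)
        tab = associate_genes(st)
        g = st.expr.index[0]
        X = sm.add_constant(st.samples[["suvmax", "initial_grade"]].astype(float))
        ols = sm.OLS(st.expr.loc[g].to_numpy(), X).fit()
        assert tab.loc[g, "coef"] == pytest.approx(ols.params["suvmax"], abs=1e-10)
        assert tab.loc[g, "p"] == pytest.approx(ols.pvalues["suvmax"], abs=1e-10)

    def test_bh_step_up_worked_example(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_global_null_type_one_error(self):
        st = make_expression_study(1000, 30, 0, beta=0.0, grade_confounding=0.0,
                                   seed=4, patient_sd=0.0)
        tab = associate_genes(st)
        assert 0.03 <= (tab["p"] < 0.05).mean() <= 0.07

    def test_multiplicity_ordering_genewise(self):
        st = make_expression_study(200, 12, 10, beta=1.0, seed=5)
        tab = associate_genes(st).dropna()
        assert (tab["p_bonferroni"] >= tab["q_bh"] - 1e-12).all()
        assert (tab["q_bh"] >= tab["p"] - 1e-12).all()
        s = tab.sort_values("p")
        assert s["q_bh"].is_monotonic_increasing

    def test_constant_gene_flagged_not_fatal(self):
        rng = np.random.default_rng(6)
        expr = rng.normal(size=(4, 10))
        expr[2] = 1.0
        st = small_study(expr, suv=rng.uniform(1, 5, 10))
        tab = associate_genes(st)
        assert not tab.loc["G2", "tested"]
        assert tab.loc["G0", "tested"]

    def test_collinear_grade_rejected(self):
        rng = np.random.default_rng(7)
        suv = rng.uniform(1, 5, 8)
        st = small_study(rng.normal(size=(3, 8)), suv=suv, grade=suv)
        with pytest.raises(ValueError, match="collinear"):
            associate_genes(st)

    def test_fdr_control_on_planted_studies(self):
        # empirical FDR at q < 0.05 stays below 0.10 over replicates
        false_disc, disc = 0, 0
        for s in range(25):
            st = make_expression_study(200, 24, 10, beta=1.5, seed=100 + s,
                                       n_timepoints_per_patient=1, patient_sd=0.0)
            tab = associate_genes(st)
            hits = tab.index[tab["q_bh"] < 0.05]
            disc += len(hits)
            false_disc += len(set(hits) - set(st.planted_genes))
        assert disc > 0
        assert false_disc / disc <= 0.10


class TestMixedCheckpointModel:
    def test_zero_between_patient_variance_matches_ols(self):
        rng = np.random.default_rng(8)
        n_pat, n_tp = 8, 3
        suv = np.repeat(rng.uniform(1, 5, n_pat), n_tp)
        pat = np.repeat([f"P{i}" for i in range(n_pat)], n_tp)
        eps = rng.normal(0, 1.0, n_pat * n_tp)
        # remove any apparent patient offset so the REML profile hits lam = 0
        eps -= pd.Series(eps).groupby(pat).transform("mean").to_numpy()
        y = 2.0 + 0.0 * suv + eps
        st = small_study(y[None, :], suv=suv, patient=list(pat),
                         tp=list(np.tile(range(n_tp), n_pat)))
        res = mixed_checkpoint_model(st, ["G0"])
        from fetpet.wbt import _ols_z
        X = np.column_stack([np.ones_like(suv), suv])
        b, cov = _ols_z(y, X)
        assert res.loc["G0", "slope"] == pytest.approx(b[1], abs=1e-6)
        assert res.loc["G0", "var_ratio"] == 0.0

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        st = make_expression_study(3, 36, 1, beta=1.0, n_timepoints_per_patient=3,
                                   seed=9, patient_sd=0.8)
        g = st.expr.index[0]
        res = mixed_checkpoint_model(st, [g])
        df = st.samples.copy()
        df["y"] = st.expr.loc[g].to_numpy()
        ml = smf.mixedlm("y ~ suvmax", df, groups=df["patient_id"]).fit(reml=True)
        assert res.loc[g, "slope"] == pytest.approx(ml.params["suvmax"], abs=1e-4)
        assert res.loc[g, "se"] == pytest.approx(ml.bse["suvmax"], rel=1e-3)

    def test_slope_recovery_with_patient_offsets(self):
        st = make_expression_study(40, 36, 40, beta=1.5, grade_confounding=0.0,
                                   n_timepoints_per_patient=3, seed=10,
                                   residual_sd=0.3, patient_sd=0.8)
        res = mixed_checkpoint_model(st, st.planted_genes)
        rel_err = (res["slope"] - 1.5).abs() / 1.5
        assert rel_err.median() <= 0.2

    def test_null_type_one_error_calibrated(self):
        rejections, n_rep = 0, 200
        for s in range(n_rep):
            st = make_expression_study(1, 24, 0, beta=0.0, grade_confounding=0.0,
                                       n_timepoints_per_patient=3, seed=200 + s,
                                       patient_sd=0.8)
            res = mixed_checkpoint_model(st, [st.expr.index[0]])
            rejections += res["p"].iloc[0] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_single_timepoint_falls_back_to_ols_with_warning(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(1, 10))
        st = small_study(y, suv=rng.uniform(1, 5, 10))
        with pytest.warns(UserWarning, match="OLS"):
            res = mixed_checkpoint_model(st, ["G0"])
        assert np.isnan(res.loc["G0", "var_ratio"])
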