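"""Whole-blood transcriptome association with tumor SUVmax.

Peripheral blood expression is used as a liquid-biopsy surrogate for tumor
metabolic activity. The analysis chain is:

1. keep the most variable genes by raw median absolute deviation (MAD),
2. per gene, regress expression on SUVmax adjusted for initial WHO grade
   (ordinal, coded 2/3/4) by ordinary least squares, testing the SUVmax
   coefficient two-sided,
3. control multiplicity with Bonferroni and Benjamini-Hochberg FDR, and
4. for designated genes (e.g. immune checkpoints) measured at repeated
   blood-draw timepoints, fit a linear model with a Gaussian per-patient
   random intercept (profiled REML) so within-patient correlation does not
   inflate the SUVmax slope test.

Samples are individual blood draws: repeated timepoints of one patient
enter the per-gene OLS as separate rows; only the random-intercept model
accounts for that correlation explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionStudy",
    "mad_filter",
    "associate_genes",
    "mixed_checkpoint_model",
]


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with per-sample metadata.

    ``expr`` rows are genes, columns are samples (already normalized /
    log-scaled); ``samples`` is indexed by sample id with columns
    ``suvmax``, ``initial_grade``, ``patient_id``, ``timepoint``.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    planted_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if list(self.expr.columns) != list(self.samples.index):
            raise ValueError("expr columns must match samples index, in order")
        required = {"suvmax", "initial_grade", "patient_id", "timepoint"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples metadata lacks columns {sorted(missing)}")
        if self.samples["suvmax"].nunique() < 2:
            raise ValueError("need at least 2 distinct suvmax values")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionStudy":
        return ExpressionStudy(self.expr.loc[list(gene_ids)], self.samples,
                               planted_genes=self.planted_genes)


def gene_mad(expr: pd.DataFrame) -> pd.Series:
    """Raw per-gene MAD: median of |x - median(x)| across samples (no 1.4826)."""
    med = expr.median(axis=1)
    return (expr.sub(med, axis=0)).abs().median(axis=1)


def mad_filter(study: ExpressionStudy, top_fraction: float = 0.10) -> ExpressionStudy:
    """Keep the ceil(top_fraction * n_genes) genes with the highest raw MAD.

    Boundary ties are broken by gene-id order, making the selection
    deterministic. The MAD ranking is invariant to per-gene location shifts
    and to positive rescaling of the whole matrix.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if study.n_genes == 0:
        raise ValueError("expression matrix is empty")
    k = math.ceil(top_fraction * study.n_genes)
    mads = gene_mad(study.expr)
    order = sorted(study.expr.index, key=lambda g: (-mads[g], str(g)))
    return study.subset_genes(order[:k])


def associate_genes(study: ExpressionStudy, grade_numeric: bool = True) -> pd.DataFrame:
    """Per-gene OLS of expression on SUVmax adjusted for initial grade.

    Returns one row per gene: coef (expression change per SUVmax unit), se,
    two-sided p from the t-test on the SUVmax coefficient, Bonferroni-
    adjusted p, and Benjamini-Hochberg q. Constant genes are flagged
    (``tested`` False) and excluded from the multiplicity count m.
    """
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples")
    suv = study.samples["suvmax"].to_numpy(float)
    grade = study.samples["initial_grade"].to_numpy(float)
    if not grade_numeric:
        grade = pd.factorize(grade)[0].astype(float)
    X = np.column_stack([np.ones_like(suv), suv, grade])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("initial grade is collinear with suvmax; model not identifiable")
    dof = study.n_samples - X.shape[1]
    if dof < 1:
        raise ValueError("not enough samples for the grade-adjusted model")

    Y = study.expr.to_numpy(float).T  # samples x genes
    tested = study.expr.std(axis=1, ddof=0).to_numpy() > 0
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # 3 x genes
    resid = Y - X @ B
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B[1] / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)

    out = pd.DataFrame({
        "coef": B[1], "se": se, "p": p,
        "tested": tested,
    }, index=study.expr.index)
    out.loc[~tested, ["coef", "se", "p"]] = np.nan
    m = int(tested.sum())
    out["p_bonferroni"] = np.nan
    out["q_bh"] = np.nan
    if m:
        pt = out.loc[tested, "p"].to_numpy()
        out.loc[tested, "p_bonferroni"] = np.minimum(pt * m, 1.0)
        out.loc[tested, "q_bh"] = multipletests(pt, method="fdr_bh")[1]
    out["kept_by_mad"] = True
    return out


# ---------------------------------------------------------------------------
# Random-intercept model for repeated-timepoint genes


def _profiled_reml_fit(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """REML fit of y = X b + u_group + eps by 1-D profiling of the variance
    ratio lam = var(u)/var(eps). Returns (b, cov_b, lam)."""
    n, p = X.shape
    codes = pd.factorize(groups)[0]
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0

    def gls(lam: float):
        V = np.eye(n) + lam * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        A = XtVi @ X
        b = np.linalg.solve(A, XtVi @ y)
        r = y - X @ b
        rss = float(r @ Vi @ r)
        return b, A, rss, V

    def neg_reml(loglam: float) -> float:
        lam = np.exp(loglam)
        _, A, rss, V = gls(lam)
        sign, logdetV = np.linalg.slogdet(V)
        _, logdetA = np.linalg.slogdet(A)
        return 0.5 * (logdetV + logdetA + (n - p) * np.log(rss))

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    # compare against the boundary lam = 0 (no between-patient variance)
    if neg_reml(-40.0) <= res.fun:
        lam = 0.0
    b, A, rss, _ = gls(lam)
    sigma2 = rss / (n - p)
    cov_b = sigma2 * np.linalg.inv(A)
    return b, cov_b, lam


def _ols_z(y: np.ndarray, X: np.ndarray):
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ b
    sigma2 = float(r @ r) / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return b, cov


def mixed_checkpoint_model(study: ExpressionStudy, gene_ids: list[str]) -> pd.DataFrame:
    """Per-gene SUVmax slope with a Gaussian per-patient random intercept.

    Fitted by restricted maximum likelihood, profiling the single variance
    ratio; inference on the slope is Wald-type against a t reference whose
    degrees of freedom respect the design: when SUVmax is constant within
    patient (the usual case — one tumor per patient), patients are the
    effective units and df = n_patients - 2; otherwise df = n_samples - 2.
    When no patient contributes more than one timepoint the random
    intercept is not identifiable and the fit falls back to plain OLS with
    a warning.
    """
    suv = study.samples["suvmax"].to_numpy(float)
    patients = study.samples["patient_id"].to_numpy()
    X = np.column_stack([np.ones_like(suv), suv])
    counts = pd.Series(patients).value_counts()
    repeated = (counts >= 2).sum() >= 2
    within_var = pd.Series(suv).groupby(patients).var(ddof=0).fillna(0.0).max()
    n_units = len(counts) if (repeated and within_var < 1e-12) else len(suv)
    dof = max(n_units - X.shape[1], 1)
    if not repeated:
        warnings.warn(
            "no repeated timepoints per patient; random intercept not "
            "identifiable, falling back to OLS", stacklevel=2
        )
    rows = []
    for gene in gene_ids:
        y = study.expr.loc[gene].to_numpy(float)
        if repeated:
            b, cov, lam = _profiled_reml_fit(y, X, patients)
        else:
            b, cov = _ols_z(y, X)
            lam = np.nan
        se = float(np.sqrt(cov[1, 1]))
        z = b[1] / se if se > 0 else np.inf
        rows.append({"gene": gene, "slope": float(b[1]), "se": se,
                     "p": float(np.clip(2.0 * stats.t.sf(abs(z), dof), 1e-300, 1.0)),
                     "var_ratio": lam})
    return pd.DataFrame(rows).set_index("gene")
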