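"""Survival machinery for SUVmax-based prognostic stratification.

Two model families act on right-censored cohorts:

* a log-logistic accelerated-failure-time (AFT) model with survival
  S(t|x) = 1 / (1 + (t/alpha(x))^beta) and log alpha(x) = mu + x'theta.
  Covariates accelerate or decelerate time; exp(-theta) is reported as an
  odds-ratio-like effect oriented so values > 1 mean worse survival.
* a Cox proportional-hazards model, maximized through the partial
  likelihood with Breslow handling of tied event times; HR = exp(beta).

On top of these sit the median split of SUVmax and the minimal-p-value
"optimal cutoff" scan: the binary split 1[SUVmax > c] is fitted at every
admissible candidate cutoff c and the cutoff with the smallest Wald p-value
is selected. The scan applies no multiplicity adjustment (the selection is
an optimistic, data-driven procedure); the full per-cutoff p-value trace is
returned so users can quantify or correct that optimism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SurvivalCohort",
    "FitResult",
    "CutoffScanResult",
    "ConvergenceError",
    "fit_loglogistic",
    "fit_coxph",
    "median_split",
    "scan_cutoffs",
    "univariate_table",
    "km_curve",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalCohort:
    """Right-censored outcomes with SUVmax and optional clinical covariates.

    ``time`` is in months measured from radiotherapy onset; ``event`` is 1
    for progression/death, 0 for censoring (lost to follow-up at the last
    contact).
    """

    time: np.ndarray
    event: np.ndarray
    suvmax: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        self.suvmax = np.asarray(self.suvmax, dtype=float)
        n = len(self.time)
        if len(self.event) != n or len(self.suvmax) != n:
            raise ValueError("time, event, suvmax must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all times must be positive")
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(n))
        elif len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")

    @property
    def n(self) -> int:
        return len(self.time)

    def design(self, covariate_names: list[str]) -> np.ndarray:
        cols = []
        for name in covariate_names:
            if name == "suvmax":
                cols.append(self.suvmax)
            elif name in self.covariates.columns:
                cols.append(self.covariates[name].to_numpy(dtype=float))
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return np.column_stack(cols) if cols else np.empty((self.n, 0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_months": self.time,
            "event": self.event.astype(int),
            "suvmax": self.suvmax,
        })
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCohort":
        extra = [c for c in df.columns if c not in ("time_months", "event", "suvmax", "id")]
        return cls(
            time=df["time_months"].to_numpy(float),
            event=df["event"].to_numpy(),
            suvmax=df["suvmax"].to_numpy(float),
            covariates=df[extra].reset_index(drop=True),
        )


@dataclass
class FitResult:
    """Coefficients, Wald inference, and effect sizes for one survival fit.

    ``params`` has one row per parameter with columns coef, se, p and, for
    covariate rows, ``effect`` (exp(-coef) for the AFT model, exp(coef) for
    Cox) oriented so values > 1 mean worse survival.
    """

    model: str
    params: pd.DataFrame
    loglik: float
    n: int
    n_events: int

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])

    def p(self, name: str) -> float:
        return float(self.params.loc[name, "p"])

    # log-logistic conveniences
    @property
    def alpha_(self) -> float:
        if self.model != "loglogistic_aft":
            raise AttributeError("alpha_ only defined for the log-logistic AFT model")
        return float(np.exp(self.params.loc["intercept", "coef"]))

    @property
    def shape_(self) -> float:
        if self.model != "loglogistic_aft":
            raise AttributeError("shape_ only defined for the log-logistic AFT model")
        return float(np.exp(self.params.loc["log_shape", "coef"]))


def _validate_fit_inputs(cohort: SurvivalCohort, X: np.ndarray, names: list[str]) -> None:
    if not cohort.event.any():
        raise ValueError("cohort has no events; the model is not identifiable")
    for j, name in enumerate(names):
        if X.shape[0] and np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")


def _wald(coefs: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coefs / se, np.inf)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return se, p


def _numeric_hessian(grad, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (grad(xp) - grad(xm)) / (2 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Log-logistic AFT


def _loglogistic_negll_grad(params: np.ndarray, logt: np.ndarray, event: np.ndarray,
                            X: np.ndarray) -> tuple[float, np.ndarray]:
    p = X.shape[1]
    mu, theta, logbeta = params[0], params[1:1 + p], params[1 + p]
    beta = np.exp(logbeta)
    la = mu + X @ theta
    u = beta * (logt - la)
    sp = np.logaddexp(0.0, u)  # softplus(u) = -log S
    s = special.expit(u)
    ll = np.where(event, logbeta - logt + u - 2.0 * sp, -sp).sum()
    g_u = np.where(event, 1.0 - 2.0 * s, -s)
    g_mu = -beta * g_u.sum()
    g_theta = -beta * (X.T @ g_u)
    g_logbeta = float((g_u * u).sum() + event.sum())
    grad = np.concatenate(([g_mu], g_theta, [g_logbeta]))
    return -ll, -grad


def fit_loglogistic(cohort: SurvivalCohort, covariate_names: list[str] | None = None,
                    max_iter: int = 500) -> FitResult:
    """Maximum-likelihood log-logistic AFT fit under right censoring.

    The censored log-likelihood sum(event*log f + (1-event)*log S) is
    maximized over (mu, theta, log beta) by quasi-Newton iteration with the
    analytic gradient; standard errors come from the observed information
    (numerically differentiated gradient) and p-values are Wald-type.
    """
    names = list(covariate_names or [])
    X = cohort.design(names)
    _validate_fit_inputs(cohort, X, names)
    logt = np.log(cohort.time)
    event = cohort.event

    x0 = np.concatenate(([np.median(logt)], np.zeros(X.shape[1]), [0.0]))
    res = optimize.minimize(
        _loglogistic_negll_grad, x0, args=(logt, event, X), jac=True,
        method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    gnorm = float(np.linalg.norm(res.jac))
    if not res.success and gnorm > 1e-3:
        raise ConvergenceError(
            f"log-logistic fit did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3g})"
        )
    coefs = res.x
    H = _numeric_hessian(lambda x: _loglogistic_negll_grad(x, logt, event, X)[1], coefs)
    cov = np.linalg.pinv(H)
    se, pvals = _wald(coefs, cov)

    index = ["intercept"] + names + ["log_shape"]
    params = pd.DataFrame({"coef": coefs, "se": se, "p": pvals}, index=index)
    params["effect"] = np.nan
    if names:
        params.loc[names, "effect"] = np.exp(-params.loc[names, "coef"])
    return FitResult("loglogistic_aft", params, loglik=-float(res.fun),
                     n=cohort.n, n_events=int(event.sum()))


def loglogistic_survival(t: np.ndarray | float, alpha: float, beta: float):
    """S(t) = 1 / (1 + (t/alpha)^beta); the median survival time equals alpha."""
    return 1.0 / (1.0 + (np.asarray(t, dtype=float) / alpha) ** beta)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


def _cox_negll_grad(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                    X: np.ndarray) -> tuple[float, np.ndarray]:
    eta = X @ beta
    if np.any(np.abs(eta) > 500):
        raise FloatingPointError("linear predictor overflow")
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")  # descending time
    t_s, e_s, X_s, w_s = time[order], event[order], X[order], w[order]
    cw = np.cumsum(w_s)
    cxw = np.cumsum(X_s * w_s[:, None], axis=0)
    ll = 0.0
    grad = np.zeros_like(beta)
    i = 0
    n = len(t_s)
    # walk distinct times descending; risk set = everything seen so far + ties
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = e_s[i:j]
        if d.any():
            m = int(d.sum())
            risk_w = cw[j - 1]
            risk_xw = cxw[j - 1]
            ll += (X_s[i:j][d] @ beta).sum() - m * np.log(risk_w)
            grad += X_s[i:j][d].sum(axis=0) - m * risk_xw / risk_w
        i = j
    return -ll, -grad


def fit_coxph(cohort: SurvivalCohort, covariate_names: list[str],
              max_iter: int = 200) -> FitResult:
    """Cox proportional-hazards fit via the Breslow partial likelihood."""
    names = list(covariate_names)
    if not names:
        raise ValueError("Cox model needs at least one covariate")
    X = cohort.design(names)
    _validate_fit_inputs(cohort, X, names)
    time, event = cohort.time, cohort.event

    try:
        res = optimize.minimize(
            _cox_negll_grad, np.zeros(X.shape[1]), args=(time, event, X), jac=True,
            method="BFGS", options={"maxiter": max_iter, "gtol": 1e-9},
        )
    except FloatingPointError:
        raise ConvergenceError(
            "Cox partial likelihood is monotone (perfect separation in risk "
            "sets); consider a penalized fit"
        )
    if np.any(np.abs(res.x) > 20):
        raise ConvergenceError(
            "Cox coefficients diverged (perfect separation in risk sets); "
            "consider a penalized fit"
        )
    gnorm = float(np.linalg.norm(res.jac))
    if not res.success and gnorm > 1e-3:
        raise ConvergenceError(f"Cox fit did not converge (gradient norm {gnorm:.3g})")
    H = _numeric_hessian(lambda b: _cox_negll_grad(b, time, event, X)[1], res.x)
    cov = np.linalg.pinv(H)
    se, pvals = _wald(res.x, cov)
    params = pd.DataFrame({"coef": res.x, "se": se, "p": pvals}, index=names)
    params["effect"] = np.exp(params["coef"])  # hazard ratio
    return FitResult("cox_ph", params, loglik=-float(res.fun),
                     n=cohort.n, n_events=int(event.sum()))


# ---------------------------------------------------------------------------
# Median split and minimal-p cutoff scan


def median_split(cohort: SurvivalCohort) -> tuple[float, np.ndarray]:
    """Split at the sample median of SUVmax; 'high' means strictly above it."""
    if cohort.n < 4:
        raise ValueError("median split needs at least 4 subjects")
    if np.ptp(cohort.suvmax) == 0:
        raise ValueError("SUVmax is constant; no split possible")
    cutoff = float(np.median(cohort.suvmax))
    return cutoff, cohort.suvmax > cutoff


@dataclass
class CutoffScanResult:
    """Per-cutoff fits of the binary SUVmax split, plus the selected optimum.

    ``trace`` holds one row per candidate cutoff (coef, se, p, effect,
    n_high); ``optimal_cutoff`` minimizes the Wald p over the grid (ties
    broken toward the smaller cutoff). No multiplicity adjustment is
    applied inside the scan.
    """

    grid: np.ndarray
    trace: pd.DataFrame
    optimal_cutoff: float
    optimal_p: float
    median_cutoff: float
    model: str


def _fit_binary_split(cohort: SurvivalCohort, high: np.ndarray, model: str) -> FitResult:
    sub = SurvivalCohort(
        time=cohort.time, event=cohort.event, suvmax=cohort.suvmax,
        covariates=pd.DataFrame({"high_suv": high.astype(float)}),
    )
    if model == "loglogistic_aft":
        return fit_loglogistic(sub, ["high_suv"])
    if model == "cox_ph":
        return fit_coxph(sub, ["high_suv"])
    raise ValueError(f"unknown model {model!r}")


def scan_cutoffs(cohort: SurvivalCohort, model: str = "loglogistic_aft",
                 min_group: int = 5) -> CutoffScanResult:
    """Minimal-p-value scan over candidate SUVmax cutoffs.

    Candidates are midpoints between consecutive distinct observed SUVmax
    values that leave at least ``min_group`` subjects on each side of the
    strict split 1[SUVmax > c].
    """
    if cohort.n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} subjects for min_group={min_group}")
    distinct = np.unique(cohort.suvmax)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    grid = np.array([
        c for c in mids
        if (cohort.suvmax > c).sum() >= min_group and (cohort.suvmax <= c).sum() >= min_group
    ])
    if grid.size == 0:
        raise ValueError("no admissible cutoff leaves min_group subjects on both sides")

    rows = []
    for c in grid:
        high = cohort.suvmax > c
        try:
            fit = _fit_binary_split(cohort, high, model)
            row = fit.params.loc["high_suv"]
            rows.append({"cutoff": c, "coef": row["coef"], "se": row["se"],
                         "p": row["p"], "effect": row["effect"],
                         "n_high": int(high.sum())})
        except (ValueError, ConvergenceError):
            rows.append({"cutoff": c, "coef": np.nan, "se": np.nan, "p": np.nan,
                         "effect": np.nan, "n_high": int(high.sum())})
    trace = pd.DataFrame(rows)
    if trace["p"].isna().all():
        raise ConvergenceError("no cutoff admitted a converged fit")
    i_opt = int(np.nanargmin(trace["p"].to_numpy()))  # first minimum = smallest cutoff
    return CutoffScanResult(
        grid=grid, trace=trace,
        optimal_cutoff=float(trace.loc[i_opt, "cutoff"]),
        optimal_p=float(trace.loc[i_opt, "p"]),
        median_cutoff=float(np.median(cohort.suvmax)),
        model=model,
    )


def univariate_table(cohort: SurvivalCohort, candidate_covariates: list[str],
                     alpha: float = 0.05) -> tuple[pd.DataFrame, list[str]]:
    """One single-covariate log-logistic fit per candidate; flag p < alpha.

    A candidate whose fit fails (constant column, non-convergence) is
    marked failed and the remaining candidates are still processed. The
    selected list feeds the multivariate Cox fit.
    """
    rows = []
    selected = []
    for name in candidate_covariates:
        try:
            fit = fit_loglogistic(cohort, [name])
            row = fit.params.loc[name]
            ok = row["p"] < alpha
            rows.append({"covariate": name, "coef": row["coef"], "se": row["se"],
                         "effect": row["effect"], "p": row["p"],
                         "status": "ok", "selected": bool(ok)})
            if ok:
                selected.append(name)
        except (ValueError, KeyError, ConvergenceError) as exc:
            rows.append({"covariate": name, "coef": np.nan, "se": np.nan,
                         "effect": np.nan, "p": np.nan,
                         "status": f"failed: {exc}", "selected": False})
    return pd.DataFrame(rows), selected


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit coordinates (time, at-risk, survival)."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    out = [{"time": 0.0, "n_risk": len(t_s), "survival": 1.0}]
    surv = 1.0
    for t in np.unique(t_s[e_s]):
        n_risk = int((t_s >= t).sum())
        d = int(((t_s == t) & e_s).sum())
        surv *= 1.0 - d / n_risk
        out.append({"time": float(t), "n_risk": n_risk, "survival": surv})
    return pd.DataFrame(out)
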