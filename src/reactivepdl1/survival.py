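"""Hazard-ratio estimation, survival curves and fixed-effects meta-analysis.

The Cox proportional-hazards fitter maximizes the Efron-approximation log
partial likelihood (Breslow selectable) by Newton-Raphson with step-halving;
standard errors come from the inverse observed information at the optimum and
95% intervals are Wald, ``exp(beta +/- 1.96*se)``. Hazard ratios are per one
log2-unit of expression, uncentered (centering does not change them).

Kaplan-Meier curves and the log-rank test delegate to lifelines; the
covariate-adjusted curves use the Breslow baseline cumulative hazard from the
Cox fit, ``S(t | x*) = exp(-H0(t) * exp(beta' x*))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import (AlignmentError, ConvergenceError, DegenerateInputError,
                     EstimationError, ValidationError)

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # fixed Wald quantile for 95% intervals


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    covariate_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    ties_method: str
    n: int
    n_events: int
    n_iterations: int = 0
    baseline_times: np.ndarray = field(default=None, repr=False)
    baseline_cumhaz: np.ndarray = field(default=None, repr=False)
    design: pd.DataFrame = field(default=None, repr=False)
    times: np.ndarray = field(default=None, repr=False)
    events: np.ndarray = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "se": self.standard_errors,
            "hr": self.hazard_ratios,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_values,
        }, index=pd.Index(self.covariate_names, name="covariate"))


@dataclass
class MetaResult:
    """Fixed-effects (inverse-variance) meta-analysis of log hazard ratios."""

    study_log_hrs: np.ndarray
    study_ses: np.ndarray
    weights: np.ndarray
    pooled_log_hr: float
    pooled_se: float
    pooled_hr: float
    ci_low: float
    ci_high: float
    p_value: float
    q_statistic: float
    i_squared: float


@dataclass
class SurvivalCurve:
    """A step survival curve starting at S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""


def _ll_grad_info(t, d, X, first, beta, ties):
    """Log partial likelihood, gradient and observed information.

    ``t`` ascending; ``first`` holds the start index of each distinct-time
    group so the risk set at a group is everything from its start onward.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilization; ll shifts cancel exactly
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    bounds = list(first) + [n]
    for k in range(len(first)):
        s, e = bounds[k], bounds[k + 1]
        dmask = d[s:e] == 1
        m = int(dmask.sum())
        if m == 0:
            continue
        S0, S1, S2 = cw[s], cwx[s], cwxx[s]
        ll += eta[s:e][dmask].sum()
        grad += X[s:e][dmask].sum(axis=0)
        wd = w[s:e][dmask].sum()
        wxd = wx[s:e][dmask].sum(axis=0)
        wxxd = wxx[s:e][dmask].sum(axis=0)
        for l in range(m):
            f = l / m if ties == "efron" else 0.0
            den = S0 - f * wd
            num1 = S1 - f * wxd
            num2 = S2 - f * wxxd
            ll -= np.log(den)
            g = num1 / den
            grad -= g
            info += num2 / den - np.outer(g, g)
    return ll, grad, info


def fit_cox(clinical: pd.DataFrame, covariates, ties: str = "efron",
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox PH model of the clinical outcomes on one or more covariates.

    Parameters
    ----------
    clinical : DataFrame with columns sample_id, time, event (cohort ignored).
    covariates : Series or DataFrame indexed by sample_id, one column per
        covariate; every clinical sample must have finite covariate values.
    ties : "efron" (default, matching R's coxph) or "breslow".
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame(name=covariates.name or "x")
    X_df = covariates.reindex(clinical["sample_id"])
    if X_df.isna().any().any():
        missing = X_df.index[X_df.isna().any(axis=1)].tolist()[:5]
        raise AlignmentError(f"covariates missing for sample(s) {missing}")
    X = X_df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite covariate values")
    names = [str(c) for c in X_df.columns]
    t = clinical["time"].to_numpy(dtype=float)
    d = clinical["event"].to_numpy(dtype=int)
    n, p = X.shape
    n_events = int(d.sum())
    if n_events == 0:
        raise EstimationError("cannot fit a Cox model with zero events")
    if p >= 1 and np.any(np.ptp(X, axis=0) == 0):
        k = int(np.argmin(np.ptp(X, axis=0)))
        raise DegenerateInputError(f"covariate {names[k]!r} is constant")

    order = np.argsort(t, kind="stable")
    t_s, d_s, X_s = t[order], d[order], X[order]
    _, first = np.unique(t_s, return_index=True)

    beta = np.zeros(p)
    ll, grad, info = _ll_grad_info(t_s, d_s, X_s, first, beta, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta, new_ll = beta, ll
        accept_tol = 1e-12 * max(1.0, abs(ll))  # float resolution at ll scale
        for _ in range(30):
            cand = beta + step
            cand_ll, cand_grad, cand_info = _ll_grad_info(
                t_s, d_s, X_s, first, cand, ties)
            if np.isfinite(cand_ll) and cand_ll >= ll - accept_tol:
                new_beta, new_ll = cand, cand_ll
                grad, info = cand_grad, cand_info
                break
            step = step / 2.0
        else:
            raise ConvergenceError(
                "step-halving failed; likelihood may be monotone in covariate "
                f"{names[int(np.argmax(np.abs(beta + step)))]!r}")
        if np.max(np.abs(new_beta)) > 50:
            k = int(np.argmax(np.abs(new_beta)))
            raise ConvergenceError(
                f"monotone partial likelihood: covariate {names[k]!r} appears "
                "to separate the risk sets (coefficient diverging)")
        delta = new_ll - ll
        beta, ll = new_beta, new_ll
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    # monotone likelihood reaches a finite supremum at a finite beta, so also
    # flag fits whose linear-predictor spread is implausibly large
    spread = np.abs(beta) * np.ptp(X, axis=0)
    if np.any(spread > 100):
        k = int(np.argmax(spread))
        raise ConvergenceError(
            f"monotone partial likelihood: covariate {names[k]!r} appears to "
            "separate the risk sets (diverging coefficient)")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    hr = np.exp(beta)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    # Breslow baseline cumulative hazard at the distinct event times
    eta = X_s @ beta
    w = np.exp(eta)
    cw = np.cumsum(w[::-1])[::-1]
    bounds = list(first) + [n]
    bt, bh = [], []
    for k in range(len(first)):
        s, e = bounds[k], bounds[k + 1]
        m = int((d_s[s:e] == 1).sum())
        if m:
            bt.append(t_s[s])
            bh.append(m / cw[s])
    baseline_times = np.asarray(bt)
    baseline_cumhaz = np.cumsum(bh)

    return CoxFit(
        covariate_names=names,
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=hr,
        ci_low=np.exp(beta - Z95 * se),
        ci_high=np.exp(beta + Z95 * se),
        p_values=pvals,
        log_partial_likelihood=float(ll),
        ties_method=ties,
        n=n,
        n_events=n_events,
        n_iterations=it,
        baseline_times=baseline_times,
        baseline_cumhaz=baseline_cumhaz,
        design=X_df.copy(),
        times=t,
        events=d,
    )


def per_cohort_hr(clinical: pd.DataFrame, expression: pd.DataFrame,
                  gene: str = "CD274", ties: str = "efron") -> pd.DataFrame:
    """Univariate Cox HR of one gene's log2 expression, fit per cohort.

    Cohorts that cannot be fit (no events, degenerate covariate,
    non-convergence) are logged and skipped, not fatal.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    covariate = expression.loc[gene]
    covariate.name = gene
    rows = []
    for cohort, sub in clinical.groupby("cohort", sort=True):
        try:
            fit = fit_cox(sub.reset_index(drop=True), covariate, ties=ties)
        except (EstimationError, ValidationError, AlignmentError) as exc:
            logger.warning("cohort %s skipped: %s", cohort, exc)
            continue
        rows.append({
            "cohort": cohort, "n": fit.n, "n_events": fit.n_events,
            "coef": fit.coefficients[0], "se": fit.standard_errors[0],
            "hr": fit.hazard_ratios[0], "ci_low": fit.ci_low[0],
            "ci_high": fit.ci_high[0], "p": fit.p_values[0],
        })
    return pd.DataFrame(rows)


def hr_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame
                   ) -> tuple[float, float]:
    """Pearson correlation of per-cohort HRs between two genes.

    Returns (r, two-sided t-test p with n-2 df). Cohort sets must match.
    """
    a = table_a.set_index("cohort")["hr"]
    b = table_b.set_index("cohort")["hr"]
    if set(a.index) != set(b.index):
        raise AlignmentError("cohort sets of the two HR tables differ")
    b = b.reindex(a.index)
    if len(a) < 3:
        raise ValidationError("need >= 3 cohorts for a correlation")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p)


def meta_fixed_effects(study_log_hrs, study_ses) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-study log hazard ratios.

    ``pooled = sum(w_i b_i) / sum(w_i)`` with ``w_i = 1/se_i^2`` and
    ``pooled_se = sum(w_i)^{-1/2}``. Cochran's Q and I^2 are reported for
    description only.
    """
    b = np.asarray(study_log_hrs, dtype=float)
    se = np.asarray(study_ses, dtype=float)
    if b.ndim != 1 or b.shape != se.shape or b.size < 1:
        raise ValidationError("need equal-length, nonempty study vectors")
    if np.any(se <= 0):
        raise ValidationError("all study standard errors must be > 0")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 and df > 0 else 0.0
    return MetaResult(
        study_log_hrs=b, study_ses=se, weights=w,
        pooled_log_hr=pooled, pooled_se=pooled_se,
        pooled_hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z95 * pooled_se)),
        ci_high=float(np.exp(pooled + Z95 * pooled_se)),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        q_statistic=q, i_squared=i2,
    )


def km_curve(clinical: pd.DataFrame, label: str = "") -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival curve for one group."""
    if len(clinical) == 0:
        raise ValidationError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical["time"], event_observed=clinical["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=int)
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=at_risk,
        label=label,
    )


def logrank(clinical_a: pd.DataFrame, clinical_b: pd.DataFrame
            ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 with 1 df, p)."""
    if len(clinical_a) == 0 or len(clinical_b) == 0:
        raise ValidationError("empty group in log-rank test")
    res = _ll_logrank(clinical_a["time"], clinical_b["time"],
                      event_observed_A=clinical_a["event"],
                      event_observed_B=clinical_b["event"])
    return float(res.test_statistic), float(res.p_value)


def _curve_from_baseline(fit: CoxFit, eta_star: float, label: str
                         ) -> SurvivalCurve:
    times = np.concatenate([[0.0], fit.baseline_times])
    surv = np.concatenate([[1.0],
                           np.exp(-fit.baseline_cumhaz * np.exp(eta_star))])
    at_risk = np.array([(fit.times >= u).sum() for u in times], dtype=int)
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk,
                         label=label)


def adjusted_curves(fit: CoxFit, display: str) -> tuple[SurvivalCurve,
                                                        SurvivalCurve]:
    """Cox-adjusted survival curves for a median split on one covariate.

    The cohort is split at the median of the displayed covariate (low =
    value <= median). Each curve is ``S0(t)^exp(beta' x*)`` with ``x*``
    holding the within-half median of the displayed covariate and the overall
    median of every other covariate — PD-L1 curves adjusted for CD8A and vice
    versa.
    """
    if fit.design is None:
        raise EstimationError("fit carries no design matrix")
    if display not in fit.covariate_names:
        raise KeyError(f"covariate {display!r} not in fit")
    X = fit.design
    disp = X[display] if display in X.columns else X.iloc[
        :, fit.covariate_names.index(display)]
    med = float(disp.median())
    halves = {"low": disp <= med, "high": disp > med}
    overall_med = X.median()
    curves = []
    for name, mask in halves.items():
        if mask.sum() == 0:
            raise ValidationError(f"{name} half of {display!r} is empty")
        x_star = overall_med.copy()
        x_star[display] = float(disp[mask].median())
        eta_star = float(np.dot(fit.coefficients,
                                x_star.reindex(X.columns).to_numpy()))
        curves.append(_curve_from_baseline(
            fit, eta_star, label=f"{display} {name} (adjusted)"))
    return curves[0], curves[1]
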