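"""Reactive-efficiency scoring: the residual of PD-L1 about its CTL prediction.

The cohort's CD8A -> PD-L1 relationship is summarized by ordinary least
squares with PD-L1 as the response. Each tumor's *reactive efficiency* is its
signed vertical residual: positive means more PD-L1 than its CTL level
predicts (an efficient reactive response), negative means less. Tumors are
stratified into residual tertiles — low_efficiency / expected /
high_efficiency — and the extreme groups are contrasted by Kaplan-Meier
curves and the log-rank test. The before/after-adjustment Cox table
(univariate vs mutually adjusted HRs of CD8A and PD-L1) exposes the
confounding structure that makes raw PD-L1 look favorable while
CTL-adjusted PD-L1 is unfavorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (DegenerateInputError, GeneNotFoundError, ValidationError)
from .survival import CoxFit, SurvivalCurve, fit_cox, km_curve, logrank

logger = logging.getLogger(__name__)

GROUPS = ("low_efficiency", "expected", "high_efficiency")


@dataclass(frozen=True)
class ReactiveLine:
    """OLS fit of PD-L1 on the CTL marker (log2 scale)."""

    slope: float
    intercept: float
    n: int
    r_squared: float
    gene_ctl: str = "CD8A"
    gene_pdl1: str = "CD274"

    def predict(self, ctl) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ctl, dtype=float)


class ReactiveEfficiencyScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator for the reactive-efficiency residual score.

    ``fit`` takes a samples x genes frame and learns the OLS line of
    ``gene_pdl1`` on ``gene_ctl`` (closed form, slope = cov/var);
    ``transform`` returns the signed residuals as an (n, 1) array and
    ``score_samples`` as a Series. ``stratify`` adds the tertile group label.
    The line may be frozen on one cohort and applied to another.
    """

    def __init__(self, gene_ctl: str = "CD8A", gene_pdl1: str = "CD274"):
        self.gene_ctl = gene_ctl
        self.gene_pdl1 = gene_pdl1

    def _xy(self, X: pd.DataFrame):
        for g in (self.gene_ctl, self.gene_pdl1):
            if g not in X.columns:
                raise GeneNotFoundError(g)
        return (X[self.gene_ctl].to_numpy(dtype=float),
                X[self.gene_pdl1].to_numpy(dtype=float))

    def fit(self, X: pd.DataFrame, y=None) -> "ReactiveEfficiencyScorer":
        x, yv = self._xy(X)
        if x.size < 3:
            raise ValidationError("need >= 3 samples to fit the line")
        sxx = np.var(x)
        if sxx == 0:
            raise DegenerateInputError(f"{self.gene_ctl} has zero variance")
        sxy = np.mean((x - x.mean()) * (yv - yv.mean()))
        self.slope_ = float(sxy / sxx)
        self.intercept_ = float(yv.mean() - self.slope_ * x.mean())
        syy = np.var(yv)
        self.r_squared_ = float(sxy ** 2 / (sxx * syy)) if syy > 0 else 1.0
        self.n_ = int(x.size)
        self.line_ = ReactiveLine(self.slope_, self.intercept_, self.n_,
                                  self.r_squared_, self.gene_ctl,
                                  self.gene_pdl1)
        return self

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        x, yv = self._xy(X)
        resid = yv - (self.intercept_ + self.slope_ * x)
        return pd.Series(resid, index=X.index, name="residual")

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_samples(X).to_numpy()[:, None]

    def stratify(self, X: pd.DataFrame) -> pd.DataFrame:
        return stratify_by_residual(self.score_samples(X))


def fit_reactive_line(expression: pd.DataFrame, gene_ctl: str = "CD8A",
                      gene_pdl1: str = "CD274") -> ReactiveLine:
    """Fit the CD8A -> PD-L1 OLS line on a genes x samples matrix."""
    scorer = ReactiveEfficiencyScorer(gene_ctl, gene_pdl1).fit(expression.T)
    return scorer.line_


def score_samples(line: ReactiveLine, expression: pd.DataFrame) -> pd.Series:
    """Signed residuals of observed PD-L1 about the line's prediction."""
    for g in (line.gene_ctl, line.gene_pdl1):
        if g not in expression.index:
            raise GeneNotFoundError(g)
    ctl = expression.loc[line.gene_ctl]
    pdl1 = expression.loc[line.gene_pdl1]
    resid = pdl1 - line.predict(ctl)
    resid.name = "residual"
    return resid


def stratify_by_residual(scores: pd.Series) -> pd.DataFrame:
    """Tertile grouping of the signed residuals.

    Residuals are ranked ascending (ties broken deterministically by sample
    id); the bottom floor(n/3) samples form ``low_efficiency``, the top
    floor(n/3) ``high_efficiency``, and the remainder the middle ``expected``
    group — sizes (k, n-2k, k) with k = floor(n/3).
    """
    n = len(scores)
    if n < 3:
        raise ValidationError("need >= 3 samples to form tertiles")
    if scores.nunique() == 1:
        logger.warning("reactive-efficiency score is degenerate "
                       "(all residuals equal); grouping by sample-id order")
    order = sorted(scores.items(), key=lambda kv: (kv[1], str(kv[0])))
    k = n // 3
    groups = {}
    for rank, (sid, _) in enumerate(order):
        if rank < k:
            groups[sid] = GROUPS[0]
        elif rank >= n - k:
            groups[sid] = GROUPS[2]
        else:
            groups[sid] = GROUPS[1]
    out = pd.DataFrame({"residual": scores,
                        "group": pd.Series(groups).reindex(scores.index)})
    out.index.name = scores.index.name or "sample_id"
    return out


@dataclass
class EfficiencyOutcome:
    """Log-rank contrast of the extreme reactive-efficiency groups."""

    chi2: float
    p_value: float
    curve_low: SurvivalCurve
    curve_high: SurvivalCurve
    curve_expected: SurvivalCurve = field(default=None, repr=False)


def efficiency_outcome(scores: pd.DataFrame, clinical: pd.DataFrame
                       ) -> EfficiencyOutcome:
    """KM curves and log-rank test of low- vs high-efficiency groups.

    The middle ("expected") group is reported as a separate curve but does
    not enter the test.
    """
    cl = clinical.set_index("sample_id")
    sub = {}
    for g in GROUPS:
        ids = scores.index[scores["group"] == g]
        sub[g] = cl.loc[cl.index.intersection(ids)].reset_index()
    low, high = sub[GROUPS[0]], sub[GROUPS[2]]
    if len(low) == 0 or len(high) == 0:
        raise ValidationError("an extreme efficiency group is empty")
    if int(low["event"].sum() + high["event"].sum()) == 0:
        raise ValidationError("no events in the extreme groups")
    chi2, p = logrank(low, high)
    mid = sub[GROUPS[1]]
    return EfficiencyOutcome(
        chi2=chi2, p_value=p,
        curve_low=km_curve(low, label=GROUPS[0]),
        curve_high=km_curve(high, label=GROUPS[2]),
        curve_expected=km_curve(mid, label=GROUPS[1]) if len(mid) else None,
    )


@dataclass
class AdjustedPrognosis:
    """Univariate and mutually adjusted Cox fits with the before/after table."""

    table: pd.DataFrame
    fit_a: CoxFit
    fit_b: CoxFit
    fit_bivariate: CoxFit


def adjusted_prognosis(expression: pd.DataFrame, clinical: pd.DataFrame,
                       gene_a: str = "CD8A", gene_b: str = "CD274",
                       ties: str = "efron") -> AdjustedPrognosis:
    """Before/after-adjustment hazard ratios of two genes.

    Fits the univariate Cox model for each gene and the bivariate model with
    both, and tabulates HRs with Wald CIs — the 'prognostic value before and
    after adjustment' comparison.
    """
    for g in (gene_a, gene_b):
        if g not in expression.index:
            raise GeneNotFoundError(g)
    cov_a = expression.loc[gene_a]
    cov_a.name = gene_a
    cov_b = expression.loc[gene_b]
    cov_b.name = gene_b
    both = pd.concat([cov_a, cov_b], axis=1)
    fit_a = fit_cox(clinical, cov_a, ties=ties)
    fit_b = fit_cox(clinical, cov_b, ties=ties)
    fit_ab = fit_cox(clinical, both, ties=ties)
    rows = []
    for gene, uni in ((gene_a, fit_a), (gene_b, fit_b)):
        j = fit_ab.covariate_names.index(gene)
        rows.append({
            "gene": gene,
            "hr_univariate": uni.hazard_ratios[0],
            "ci_low_univariate": uni.ci_low[0],
            "ci_high_univariate": uni.ci_high[0],
            "p_univariate": uni.p_values[0],
            "hr_adjusted": fit_ab.hazard_ratios[j],
            "ci_low_adjusted": fit_ab.ci_low[j],
            "ci_high_adjusted": fit_ab.ci_high[j],
            "p_adjusted": fit_ab.p_values[j],
        })
    return AdjustedPrognosis(table=pd.DataFrame(rows), fit_a=fit_a,
                             fit_b=fit_b, fit_bivariate=fit_ab)
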