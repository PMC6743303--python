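"""Inter-tumor descriptive statistics and TME quadrant classification.

Tumors are divided into four tumor-microenvironment (TME) classes by the
median expression of a CTL marker (CD8A) and PD-L1:

* TME I   — CD8A-low,  PD-L1-low
* TME II  — CD8A-high, PD-L1-high
* TME III — CD8A-low,  PD-L1-high (more PD-L1 than its CTL level suggests)
* TME IV  — CD8A-high, PD-L1-low

"Low" means <= median, so odd and even cohort sizes both partition cleanly
and the labels are invariant under any strictly increasing per-gene
transform. The I/II naming of the two concordant quadrants is a package
convention (only III and IV are fixed by the field's usage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (DegenerateInputError, GeneNotFoundError, ValidationError)

logger = logging.getLogger(__name__)

TME_LABELS = ("I", "II", "III", "IV")


@dataclass
class TmeAssignment:
    """Per-sample TME quadrant labels and the median thresholds used."""

    labels: pd.Series
    median_ctl: float
    median_pdl1: float

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(TME_LABELS, fill_value=0)


class TmeClassifier(BaseEstimator):
    """Median-split TME quadrant classifier (sklearn-style estimator).

    ``fit`` learns the per-gene medians from a samples x genes frame;
    ``predict`` assigns each sample one of the labels I-IV. The thresholds
    generalize to new samples, so a classifier fit on one cohort can label
    another.
    """

    def __init__(self, gene_ctl: str = "CD8A", gene_pdl1: str = "CD274"):
        self.gene_ctl = gene_ctl
        self.gene_pdl1 = gene_pdl1

    def _check_X(self, X: pd.DataFrame) -> pd.DataFrame:
        for g in (self.gene_ctl, self.gene_pdl1):
            if g not in X.columns:
                raise GeneNotFoundError(g)
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "TmeClassifier":
        X = self._check_X(X)
        if len(X) < 2:
            raise ValidationError("need >= 2 samples to set median thresholds")
        self.median_ctl_ = float(X[self.gene_ctl].median())
        self.median_pdl1_ = float(X[self.gene_pdl1].median())
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        X = self._check_X(X)
        ctl_low = X[self.gene_ctl] <= self.median_ctl_
        pdl1_low = X[self.gene_pdl1] <= self.median_pdl1_
        labels = np.where(ctl_low & pdl1_low, "I",
                          np.where(~ctl_low & ~pdl1_low, "II",
                                   np.where(ctl_low, "III", "IV")))
        return pd.Series(labels, index=X.index, name="tme")


def assign_tme(expression: pd.DataFrame, gene_ctl: str = "CD8A",
               gene_pdl1: str = "CD274") -> TmeAssignment:
    """Label every sample of a genes x samples matrix with its TME quadrant."""
    clf = TmeClassifier(gene_ctl=gene_ctl, gene_pdl1=gene_pdl1)
    X = expression.T
    clf.fit(X)
    return TmeAssignment(labels=clf.predict(X),
                         median_ctl=clf.median_ctl_,
                         median_pdl1=clf.median_pdl1_)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mean_log2_gap(group_a, group_b) -> tuple[float, float]:
    """Mean log2 expression gap and the corresponding fold change.

    ``delta_log2 = mean(a) - mean(b)``; ``fold_change = 2**delta_log2``
    (e.g. a gap of 3.83 log2 units is a 14.2-fold difference).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    delta = float(a.mean() - b.mean())
    return delta, float(2.0 ** delta)


def wilcoxon_rank_sum(group_a, group_b, alternative: str = "two-sided",
                      exact_threshold: int = 12) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two independent groups.

    Returns the rank-sum statistic of group a and the p-value: exact
    enumeration when ``n_a + n_b <= exact_threshold`` and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= exact_threshold and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Fisher exact test on a 2x2 table of non-negative counts.

    Returns the sample odds ratio ``ad/bc`` and the two-sided p-value under
    the minimum-likelihood rule (sum of hypergeometric probabilities of
    tables with fixed margins whose point probability does not exceed the
    observed one) — the convention of R's fisher.test.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValidationError("need a 2x2 table of non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("all margins of the 2x2 table must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)
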