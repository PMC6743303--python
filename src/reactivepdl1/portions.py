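"""Intratumoral analysis of paired tumor portions.

TCGA barcodes identify multiple physical portions of the same tumor.
Replicate columns of the same portion are averaged first; each tumor with at
least two portions then contributes exactly one portion pair. Within a pair
the two portions' expression differences (portion_a minus portion_b, log2
scale) are compared: if the CTL marker and PD-L1 move in the same direction
the pair is *concordant*, and an exact binomial test against 0.5 asks whether
concordance exceeds chance — the intratumoral signature of reactive PD-L1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (BarcodeParseError, DegenerateInputError, FormatError,
                     GeneNotFoundError, ValidationError)
from .io import parse_barcode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PortionPair:
    """Expression deltas between two portions of one tumor.

    ``portion_a`` is the portion with the higher CTL-marker (CD8A) value, so
    ``delta_ctl >= 0``; concordance counting is invariant to this
    orientation (both deltas negate together).
    """

    patient_id: str
    portion_a: str
    portion_b: str
    delta_ctl: float
    delta_pdl1: float
    delta_ifng: float


@dataclass
class ConcordanceResult:
    """Direction-concordance counts and the exact binomial p-value."""

    n_concordant: int
    n_discordant: int
    n_tied: int
    n_pairs_used: int
    p_value: float
    sidedness: str


def average_portion_replicates(expression: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate columns sharing (patient, sample, portion).

    Column names must parse as TCGA-style barcodes with a portion field;
    offenders are listed in one error. Output columns form a MultiIndex
    (patient_id, sample_code, portion) and values are arithmetic means of the
    replicate columns.
    """
    keys, bad = [], []
    for col in expression.columns:
        try:
            bc = parse_barcode(str(col))
            if not bc.portion:
                raise BarcodeParseError(f"barcode {col!r} lacks a portion field")
            keys.append(bc.portion_key)
        except BarcodeParseError:
            bad.append(str(col))
    if bad:
        raise FormatError(f"unparseable barcode(s): {bad}")
    mi = pd.MultiIndex.from_tuples(
        keys, names=["patient_id", "sample_code", "portion"])
    by_portion = expression.T.set_axis(mi, axis=0)
    out = by_portion.groupby(level=["patient_id", "sample_code", "portion"],
                             sort=True).mean().T
    n_rep = expression.shape[1] - out.shape[1]
    if n_rep:
        logger.info("averaged %d replicate column(s) into portions", n_rep)
    return out


def find_portion_pairs(expression: pd.DataFrame, gene_ctl: str = "CD8A",
                       gene_pdl1: str = "CD274", gene_ifng: str = "IFNG"
                       ) -> list[PortionPair]:
    """Emit one portion pair per tumor with >= 2 distinct portions.

    ``expression`` must be portion-collapsed (MultiIndex columns from
    :func:`average_portion_replicates`). Tumors with more than two portions
    contribute the pair of the two lexicographically smallest portion codes
    only, preserving one independent pair per tumor for the binomial test.
    """
    if not isinstance(expression.columns, pd.MultiIndex):
        raise ValidationError("expected a portion-collapsed matrix "
                              "(MultiIndex columns)")
    for g in (gene_ctl, gene_pdl1):
        if g not in expression.index:
            raise GeneNotFoundError(g)
    has_ifng = gene_ifng in expression.index
    pairs: list[PortionPair] = []
    cols = pd.DataFrame(index=expression.columns).reset_index()
    for (patient, sample), grp in cols.groupby(["patient_id", "sample_code"],
                                               sort=True):
        portions = sorted(grp["portion"].unique())
        if len(portions) < 2:
            continue
        pa, pb = portions[0], portions[1]
        col_a = (patient, sample, pa)
        col_b = (patient, sample, pb)
        d_ctl = expression.loc[gene_ctl, col_a] - expression.loc[gene_ctl, col_b]
        if d_ctl < 0:  # orient so portion_a carries the higher CTL marker
            pa, pb = pb, pa
            col_a, col_b = col_b, col_a
            d_ctl = -d_ctl
        d_pdl1 = expression.loc[gene_pdl1, col_a] - expression.loc[gene_pdl1, col_b]
        d_ifng = (expression.loc[gene_ifng, col_a]
                  - expression.loc[gene_ifng, col_b]) if has_ifng else math.nan
        pairs.append(PortionPair(
            patient_id=patient, portion_a=pa, portion_b=pb,
            delta_ctl=float(d_ctl), delta_pdl1=float(d_pdl1),
            delta_ifng=float(d_ifng)))
    return pairs


def binomial_test(k: int, n: int, p0: float = 0.5,
                  sidedness: str = "one-sided") -> float:
    """Exact binomial test of k successes in n trials against rate p0.

    ``one-sided`` (default) is the upper tail P(X >= k); ``two-sided`` sums
    the point probabilities not exceeding that of k (minimum-likelihood
    rule); ``less`` gives the lower tail. No normal approximation.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValidationError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValidationError(f"invalid counts k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError("p0 must lie strictly in (0, 1)")
    alt = {"one-sided": "greater", "greater": "greater",
           "less": "less", "two-sided": "two-sided"}.get(sidedness)
    if alt is None:
        raise ValidationError(f"unknown sidedness {sidedness!r}")
    return float(stats.binomtest(int(k), int(n), p0, alternative=alt).pvalue)


def direction_concordance(pairs: list[PortionPair],
                          delta_x: str = "delta_ctl",
                          delta_y: str = "delta_pdl1",
                          sidedness: str = "one-sided") -> ConcordanceResult:
    """Binomial test of same-direction movement of two genes across pairs.

    A pair is concordant iff ``delta_x * delta_y > 0``; pairs where either
    delta is exactly zero count as ties and are excluded from the test
    (deterministic and conservative). The default sidedness is one-sided
    because the reactive hypothesis pre-specifies the direction.
    """
    if not pairs:
        raise ValidationError("need at least one pair")
    dx = np.array([getattr(p, delta_x) for p in pairs], dtype=float)
    dy = np.array([getattr(p, delta_y) for p in pairs], dtype=float)
    prod = dx * dy
    tied = prod == 0
    used = ~tied
    if not used.any():
        raise DegenerateInputError("every pair is tied (a zero delta)")
    n_conc = int((prod[used] > 0).sum())
    n_used = int(used.sum())
    p = binomial_test(n_conc, n_used, 0.5, sidedness=sidedness)
    return ConcordanceResult(
        n_concordant=n_conc, n_discordant=n_used - n_conc,
        n_tied=int(tied.sum()), n_pairs_used=n_used,
        p_value=p, sidedness=sidedness)


def paired_t_test(deltas) -> tuple[float, int, float]:
    """Paired t-test on a vector of within-pair differences.

    Returns ``(t, df, two-sided p)`` with ``t = mean/(sd/sqrt(n))`` and
    ``df = n - 1``. A zero sample standard deviation is a degenerate input,
    not evidence (no p = 0).
    """
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValidationError("need >= 2 paired differences")
    if np.std(d, ddof=1) == 0:
        raise DegenerateInputError("zero standard deviation of differences")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), int(d.size - 1), float(res.pvalue)
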