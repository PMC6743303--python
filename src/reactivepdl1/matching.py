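"""CD8A-matched comparison of PD-L1-amplified tumors vs copy-number controls.

Amplified tumors systematically differ from controls in their CTL level, so a
raw comparison of PD-L1 expression confounds copy number with CTL. Greedy
nearest-neighbor matching on CD8A expression (without replacement, within a
caliper) builds pairs with almost identical CTL marker levels; the paired
t-test on the within-pair PD-L1 difference then isolates the copy-number
effect on the induction response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import GeneNotFoundError, ValidationError
from .portions import paired_t_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchedPair:
    """One case (PD-L1 amplified) matched to a control on the covariate."""

    case_id: str
    control_id: str
    abs_delta_ctl: float
    delta_pdl1: float = math.nan  # case minus control; filled from expression


@dataclass
class MatchedComparison:
    """Paired t-test summary of the within-pair PD-L1 differences."""

    n_pairs: int
    mean_delta: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p_value: float


def match_by_covariate(cases: pd.Series, controls: pd.Series,
                       caliper: float = 0.1) -> list[MatchedPair]:
    """Greedy nearest-neighbor matching without replacement.

    Cases are processed in increasing covariate order (ties by sample id);
    each takes the unused control minimizing the absolute covariate
    difference (ties by control id), and the pair is kept only if the
    difference is within the caliper — otherwise the case goes unmatched and
    the control stays available. Deterministic, and invariant to the input
    ordering of either series.
    """
    if caliper <= 0:
        raise ValidationError("caliper must be > 0")
    for name, s in (("cases", cases), ("controls", controls)):
        if not np.all(np.isfinite(s.to_numpy(dtype=float))):
            raise ValidationError(f"non-finite covariate among {name}")
    if len(cases) == 0 or len(controls) == 0:
        logger.info("matching: empty case or control set, no pairs")
        return []
    case_order = sorted(cases.items(), key=lambda kv: (kv[1], str(kv[0])))
    ctrl = sorted(controls.items(), key=lambda kv: (kv[1], str(kv[0])))
    ctrl_ids = [str(k) for k, _ in ctrl]
    ctrl_vals = np.array([v for _, v in ctrl], dtype=float)
    used = np.zeros(len(ctrl), dtype=bool)
    pairs: list[MatchedPair] = []
    for cid, cval in case_order:
        free = ~used
        if not free.any():
            break
        diffs = np.abs(ctrl_vals - cval)
        diffs[used] = np.inf
        best = np.flatnonzero(diffs == diffs.min())
        j = min(best, key=lambda i: ctrl_ids[i])  # tie-break on control id
        if diffs[j] <= caliper:
            used[j] = True
            pairs.append(MatchedPair(case_id=str(cid), control_id=ctrl_ids[j],
                                     abs_delta_ctl=float(diffs[j])))
    logger.info("matched %d of %d cases (caliper %g)", len(pairs),
                len(cases), caliper)
    return pairs


def attach_expression_delta(pairs: list[MatchedPair], expression: pd.DataFrame,
                            gene: str = "CD274") -> list[MatchedPair]:
    """Fill each pair's delta_pdl1 with case-minus-control expression."""
    if gene not in expression.index:
        raise GeneNotFoundError(gene)
    row = expression.loc[gene]
    return [replace(p, delta_pdl1=float(row[p.case_id] - row[p.control_id]))
            for p in pairs]


def match_amplified_tumors(expression: pd.DataFrame, cnv: pd.DataFrame,
                           gene_ctl: str = "CD8A", gene_pdl1: str = "CD274",
                           caliper: float = 0.1,
                           control_codes: tuple[int, ...] = (0,)
                           ) -> list[MatchedPair]:
    """Match PD-L1-amplified tumors (code 2) to controls on CD8A expression.

    Controls default to copy-neutral samples (code 0); ``control_codes`` can
    admit any non-amplified code. The caliper is in log2 expression units.
    """
    if gene_ctl not in expression.index:
        raise GeneNotFoundError(gene_ctl)
    if 2 in control_codes:
        raise ValidationError("control codes must not include amplification")
    codes = cnv.set_index("sample_id")["code"]
    codes = codes[codes.index.isin(expression.columns)]
    ctl = expression.loc[gene_ctl]
    cases = ctl[codes.index[codes == 2]]
    controls = ctl[codes.index[codes.isin(control_codes)]]
    pairs = match_by_covariate(cases, controls, caliper=caliper)
    return attach_expression_delta(pairs, expression, gene=gene_pdl1)


def compare_matched(pairs: list[MatchedPair]) -> MatchedComparison:
    """Paired t-test of PD-L1 expression across matched pairs."""
    if len(pairs) < 2:
        raise ValidationError("need >= 2 matched pairs")
    deltas = np.array([p.delta_pdl1 for p in pairs], dtype=float)
    if np.any(np.isnan(deltas)):
        raise ValidationError("pairs lack expression deltas; "
                              "run attach_expression_delta first")
    t, df, p = paired_t_test(deltas)
    from scipy import stats as _st
    half = _st.t.ppf(0.975, df) * deltas.std(ddof=1) / math.sqrt(deltas.size)
    m = float(deltas.mean())
    return MatchedComparison(n_pairs=deltas.size, mean_delta=m,
                             ci_low=m - half, ci_high=m + half,
                             t=t, df=df, p_value=p)
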