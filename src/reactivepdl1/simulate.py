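"""Synthetic cohorts with the statistical structure of reactive PD-L1.

The generative model encodes the adaptive-immune-resistance picture as a
linear-Gaussian system on the log2 expression scale:

* a latent cytotoxic T-lymphocyte level ``C_i ~ Normal(mu_ctl, sd_ctl^2)``;
* ``CD8A_i = C_i + Normal(0, sd_measure^2)`` — CD8A proxies CTL with
  measurement noise;
* for *reactive* tumors ``PDL1_i = alpha + kappa_state * C_i +
  Normal(0, sd_pdl1^2)`` where the induction slope ``kappa_state`` depends on
  the PD-L1 copy-number state (amplification enhances the response to CTL,
  deletion dampens it — the copy number acts on the slope, not the baseline);
* a minority fraction of *constitutive* tumors express
  ``PDL1_i = const_level + Normal(0, sd_pdl1^2)`` independently of C;
* ``IFNG_i = C_i + noise`` (interferon-gamma tracks the T-cell response) and
  ``IFNGR1_i`` is independent noise plus a configurable shift;
* survival follows a proportional-hazards model with exponential event times,
  rate ``baseline_hazard * exp(beta_ctl*C_i + beta_pdl1*PDL1_i)``, and an
  independent exponential censoring time with rate ``censor_rate``.

An immunotherapy-like cohort replaces the hazard linear predictor by
``gamma_residual * R_i`` with ``R_i = PDL1_i - (alpha + kappa_state*C_i)``:
outcome depends on the *residual* reactive efficiency, not on raw PD-L1.

All generators derive their randomness from ``SimulationParams.seed`` through
spawned substreams, so identical parameters reproduce identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CLINICAL_COLUMNS

logger = logging.getLogger(__name__)

#: genes every synthetic expression matrix carries
GENES = ("CD8A", "CD274", "IFNG", "IFNGR1")


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of the synthetic tumor cohorts.

    Expression-side parameters are on the log2 scale; survival-side rates are
    per unit study time. Defaults describe a strongly reactive regime: tight
    CTL->PD-L1 coupling with a small constitutive minority and the favorable
    CTL / unfavorable direct PD-L1 hazard coefficients under which univariate
    and CTL-adjusted PD-L1 hazard ratios sit on opposite sides of 1.
    """

    n_samples: int = 500
    mu_ctl: float = 2.0
    sd_ctl: float = 1.0
    sd_measure: float = 0.2
    alpha: float = 1.0
    kappa_neutral: float = 0.9
    kappa_amp: float = 1.5
    kappa_del: float = 0.45
    sd_pdl1: float = 0.3
    frac_constitutive: float = 0.05
    const_level: float = 4.0
    frac_amp: float = 0.05
    frac_del: float = 0.05
    beta_ctl: float = -0.5
    beta_pdl1: float = 0.4
    gamma_residual: float = 0.8
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    ifngr1_shift: float = 0.0
    cnv_additive: bool = False
    cnv_additive_amp: float = 1.0
    cnv_additive_del: float = -1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        for name in ("sd_ctl", "sd_measure", "sd_pdl1"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("frac_constitutive", "frac_amp", "frac_del"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.frac_amp + self.frac_del > 1.0:
            raise ValidationError("frac_amp + frac_del must be <= 1")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValidationError("baseline_hazard and censor_rate must be > 0")

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """One generated cohort: expression, clinical, CNV and the latent truth.

    ``truth`` records per sample the latent CTL value, the constitutive flag,
    the CNV code, the induction slope used, the reactive prediction residual
    and the hazard linear predictor — the oracle for parameter-recovery tests.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    cnv: pd.DataFrame
    truth: pd.DataFrame
    params: SimulationParams

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def _kappa_and_shift(params: SimulationParams, codes: np.ndarray):
    """Per-sample induction slope and additive shift for the CNV state."""
    if params.cnv_additive:
        kappa = np.full(codes.shape, params.kappa_neutral)
        shift = np.where(codes == 2, params.cnv_additive_amp,
                         np.where(codes == -2, params.cnv_additive_del, 0.0))
    else:
        kappa = np.where(codes == 2, params.kappa_amp,
                         np.where(codes == -2, params.kappa_del,
                                  params.kappa_neutral))
        shift = np.zeros_like(kappa)
    return kappa, shift


def _expression_block(params: SimulationParams, n: int, rng: np.random.Generator,
                      ctl: np.ndarray | None = None):
    """Draw CNV states, mixture flags and the four-gene expression block."""
    r_ctl, r_state, r_noise = rng.spawn(3)
    if ctl is None:
        ctl = params.mu_ctl + params.sd_ctl * r_ctl.standard_normal(n)
    u = r_state.random(n)
    codes = np.where(u < params.frac_amp, 2,
                     np.where(u < params.frac_amp + params.frac_del, -2, 0))
    constitutive = r_state.random(n) < params.frac_constitutive
    kappa, shift = _kappa_and_shift(params, codes)

    cd8a = ctl + params.sd_measure * r_noise.standard_normal(n)
    ifng = ctl + params.sd_measure * r_noise.standard_normal(n)
    ifngr1 = params.ifngr1_shift + r_noise.standard_normal(n)
    reactive_mean = params.alpha + kappa * ctl + shift
    pdl1 = np.where(constitutive, params.const_level, reactive_mean)
    pdl1 = pdl1 + params.sd_pdl1 * r_noise.standard_normal(n)
    residual = pdl1 - reactive_mean
    return {
        "ctl": ctl, "codes": codes, "constitutive": constitutive,
        "kappa": kappa, "cd8a": cd8a, "ifng": ifng, "ifngr1": ifngr1,
        "pdl1": pdl1, "residual": residual,
    }


def _survival_block(params: SimulationParams, lp: np.ndarray,
                    rng: np.random.Generator):
    """Exponential PH event times vs independent exponential censoring."""
    n = lp.shape[0]
    rate = params.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / params.censor_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _assemble(params, ids, blk, time, event, lp, cohort_label) -> SyntheticCohort:
    expression = pd.DataFrame(
        [blk["cd8a"], blk["pdl1"], blk["ifng"], blk["ifngr1"]],
        index=list(GENES), columns=ids,
    )
    expression.index.name = "gene_id"
    clinical = pd.DataFrame({
        "sample_id": ids, "time": time, "event": event,
        "cohort": cohort_label,
    }).loc[:, list(CLINICAL_COLUMNS)]
    cnv = pd.DataFrame({"sample_id": ids, "code": blk["codes"]})
    truth = pd.DataFrame({
        "sample_id": ids,
        "ctl": blk["ctl"],
        "constitutive": blk["constitutive"].astype(int),
        "cnv_code": blk["codes"],
        "kappa": blk["kappa"],
        "residual": blk["residual"],
        "linear_predictor": lp,
    })
    return SyntheticCohort(expression, clinical, cnv, truth, params)


def generate_cohort(params: SimulationParams,
                    cohort_label: str = "cohort1",
                    rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Generate one cohort under the reactive PD-L1 + PH survival model."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    r_expr, r_surv = rng.spawn(2)
    n = params.n_samples
    blk = _expression_block(params, n, r_expr)
    lp = params.beta_ctl * blk["ctl"] + params.beta_pdl1 * blk["pdl1"]
    time, event = _survival_block(params, lp, r_surv)
    ids = [f"{cohort_label}-{i:04d}" for i in range(n)]
    cohort = _assemble(params, ids, blk, time, event, lp, cohort_label)
    logger.info("generated cohort %s: n=%d, events=%d, seed=%d",
                cohort_label, n, int(event.sum()), params.seed)
    return cohort


def generate_immunotherapy_cohort(params: SimulationParams,
                                  n: int | None = None,
                                  cohort_label: str = "immuno",
                                  rng: np.random.Generator | None = None
                                  ) -> SyntheticCohort:
    """Cohort whose hazard depends only on the reactive-efficiency residual.

    ``hazard_i = baseline_hazard * exp(gamma_residual * R_i)`` with
    ``R_i = PDL1_i - (alpha + kappa_state*C_i)``; raw PD-L1 and CD8A carry no
    direct effect, emulating a checkpoint-blockade cohort where outcome tracks
    how efficiently PD-L1 reacted to CTL rather than its absolute level.
    """
    params.validate()
    if n is not None:
        params = params.with_(n_samples=n)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    r_expr, r_surv = rng.spawn(2)
    blk = _expression_block(params, params.n_samples, r_expr)
    lp = params.gamma_residual * blk["residual"]
    time, event = _survival_block(params, lp, r_surv)
    ids = [f"{cohort_label}-{i:04d}" for i in range(params.n_samples)]
    return _assemble(params, ids, blk, time, event, lp, cohort_label)


def generate_paired_portions(params: SimulationParams, n_pairs: int,
                             sd_within: float,
                             cohort_label: str = "PT") -> SyntheticCohort:
    """Two portions per tumor, ids in parseable TCGA barcode form.

    The tumor-level CTL value is drawn once; each portion perturbs it by
    ``Normal(0, sd_within^2)`` and expression is generated from the
    portion-level CTL, so within-tumor CD8A and PD-L1 differences co-vary
    through the shared induction slope. CNV state and the constitutive flag
    are tumor-level. Sample ids look like ``TCGA-PT-0007-01A-11R-SIM`` /
    ``...-21R-SIM`` (portions 11 and 21 of the same tumor).
    """
    params.validate()
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    if sd_within < 0:
        raise ValidationError("sd_within must be >= 0")
    rng = np.random.default_rng(params.seed)
    r_tumor, r_portion, r_surv = rng.spawn(3)

    ctl_tumor = params.mu_ctl + params.sd_ctl * r_tumor.standard_normal(n_pairs)
    u = r_tumor.random(n_pairs)
    codes_tumor = np.where(u < params.frac_amp, 2,
                           np.where(u < params.frac_amp + params.frac_del, -2, 0))
    const_tumor = r_tumor.random(n_pairs) < params.frac_constitutive

    n = 2 * n_pairs
    ctl = np.repeat(ctl_tumor, 2) + sd_within * r_portion.standard_normal(n)
    codes = np.repeat(codes_tumor, 2)
    constitutive = np.repeat(const_tumor, 2)
    kappa, shift = _kappa_and_shift(params, codes)

    cd8a = ctl + params.sd_measure * r_portion.standard_normal(n)
    ifng = ctl + params.sd_measure * r_portion.standard_normal(n)
    ifngr1 = params.ifngr1_shift + r_portion.standard_normal(n)
    reactive_mean = params.alpha + kappa * ctl + shift
    pdl1 = np.where(constitutive, params.const_level, reactive_mean)
    pdl1 = pdl1 + params.sd_pdl1 * r_portion.standard_normal(n)
    blk = {"ctl": ctl, "codes": codes, "constitutive": constitutive,
           "kappa": kappa, "cd8a": cd8a, "ifng": ifng, "ifngr1": ifngr1,
           "pdl1": pdl1, "residual": pdl1 - reactive_mean}

    lp = params.beta_ctl * ctl + params.beta_pdl1 * pdl1
    time, event = _survival_block(params, lp, r_surv)
    portion_codes = ("11", "21")
    ids = [f"TCGA-{cohort_label}-{i:04d}-01A-{portion_codes[j]}R-SIM"
           for i in range(n_pairs) for j in range(2)]
    return _assemble(params, ids, blk, time, event, lp, cohort_label)


def generate_multi_cohort(params: SimulationParams, n_cohorts: int,
                          per_cohort_n: int) -> list[SyntheticCohort]:
    """Independent cohorts sharing the hazard coefficients (multi-study setup).

    Cohort labels are distinct; sampling is independent across cohorts but all
    cohorts inherit the same generating betas, as in a multi-cohort
    meta-analysis of one common effect.
    """
    params.validate()
    if n_cohorts < 1:
        raise ValidationError("n_cohorts must be >= 1")
    rng = np.random.default_rng(params.seed)
    streams = rng.spawn(n_cohorts)
    cohorts = []
    for k, sub in enumerate(streams, start=1):
        label = f"cohort{k:02d}"
        p_k = params.with_(n_samples=per_cohort_n)
        cohorts.append(generate_cohort(p_k, cohort_label=label, rng=sub))
    return cohorts


def params_to_dict(params: SimulationParams) -> dict:
    """JSON-serializable view of the generating parameters."""
    return asdict(params)
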