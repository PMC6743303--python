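# Methods

## The question and the quantities

PD-L1 (CD274) transcription can be induced by interferon-gamma released
during a cytotoxic T-lymphocyte (CTL) attack — *reactive* expression under
the adaptive-immune-resistance model — or driven by tumor-intrinsic
mechanisms — *constitutive* expression. The package quantifies the
consequences of the reactive reading on bulk expression + survival data:

1. if PD-L1 mostly tracks CTL, its univariate prognostic value must be
   concordant with CD8A's across cohorts;
2. within one tumor, portions with more CTL should carry more PD-L1;
3. copy-number gains should change the *slope* of the CTL→PD-L1 response,
   not install CTL-independent expression;
4. what carries independent prognostic information is not the PD-L1 level
   but its *reactive efficiency*: the signed residual of observed PD-L1
   about the cohort's CD8A→PD-L1 regression line.

## Generative model

All expression is on the log2 scale (log2 FPKM conventions; raw FPKM should
enter as `log2(FPKM+1)`). For sample *i*:

* latent CTL `C_i ~ N(mu_ctl, sd_ctl²)`; `CD8A_i = C_i + N(0, sd_measure²)`;
  `IFNG_i = C_i + N(0, sd_measure²)`; `IFNGR1_i` is independent noise plus a
  configurable shift.
* copy-number state drawn with probabilities `frac_amp` (GISTIC code 2),
  `frac_del` (code −2), else neutral. The state sets the induction slope
  `kappa_state` (`kappa_amp > kappa_neutral > kappa_del`): amplification
  *enhances the response to CTL* multiplicatively on the slope rather than
  adding a CTL-independent offset. An additive mode
  (`cnv_additive=True`) is available for sensitivity analysis.
* reactive tumors: `PDL1_i = alpha + kappa_state·C_i + N(0, sd_pdl1²)`;
  a fraction `frac_constitutive` instead expresses
  `PDL1_i = const_level + N(0, sd_pdl1²)`, independent of `C`.
* survival: exponential event times with rate
  `baseline_hazard · exp(beta_ctl·C_i + beta_pdl1·PDL1_i)`, independent
  exponential censoring with rate `censor_rate`; `time = min`, `event`
  indicates the event came first. Exponential times are the simplest
  PH-compatible choice; nothing downstream depends on the baseline shape.
* the immunotherapy-like cohort replaces the linear predictor by
  `gamma_residual · R_i` with `R_i = PDL1_i − (alpha + kappa_state·C_i)`:
  outcome depends on the residual only, so raw PD-L1 and CD8A carry no
  direct effect.

Randomness flows from `SimulationParams.seed` through spawned NumPy
substreams (one per component), so identical parameters give identical
cohorts and enlarging one block does not perturb another.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `mu_ctl`, `sd_ctl` | 2.0, 1.0 | centered log2 scale, unit CTL spread |
| `sd_measure` | 0.2 | CD8A is a close but imperfect CTL proxy |
| `alpha`, `kappa_neutral` | 1.0, 0.9 | strong reactive coupling (implied r(CD8A,PD-L1) ≈ 0.8 at the mixture defaults) |
| `kappa_amp`, `kappa_del` | 1.5, 0.45 | gain strengthens, loss weakens induction |
| `sd_pdl1` | 0.3 | intrinsic PD-L1 noise about the response line |
| `frac_constitutive`, `const_level` | 0.05, 4.0 | constitutive expression is real but uncommon; when present it is high and CTL-independent |
| `frac_amp`, `frac_del` | 0.05, 0.05 | high-level CNV calls are rare |
| `beta_ctl`, `beta_pdl1` | −0.5, +0.4 | favorable CTL effect outweighing the direct unfavorable PD-L1 effect |
| `gamma_residual` | 0.8 | a deliberately free parameter: no external estimate exists for the residual effect in checkpoint-blockade cohorts |
| `baseline_hazard`, `censor_rate` | 0.1, 0.05 | roughly two-thirds of subjects reach the event |

The defaults were fixed once by analytic design (marginal HR calculations
and power estimates at cohorts of a few hundred samples) and describe a
strongly reactive regime; the default coupling is deliberately tighter than
typical pan-cancer bulk correlations (~0.5–0.65), because it is the
mechanism under study, and can be relaxed through `sd_pdl1`,
`frac_constitutive` and `sd_measure`.

What the generator does **not** emulate: absolute FPKM distributions,
batch/platform effects, cancer-type composition, non-exponential hazards,
or informative censoring. Tests passing on these cohorts show the pipeline
recovers the structure it assumes; they do not certify behavior on real
data with those additional features.

## Estimation and testing machinery

* **Cox PH** (`survival.fit_cox`): in-package Newton–Raphson maximizer of
  the Efron-approximation log partial likelihood (Breslow selectable).
  Step-halving guards each iteration; convergence when the log-likelihood
  change falls below 1e-9 (acceptance of a candidate step uses a
  scale-aware tolerance, 1e-12·|ll|, to stay robust at |ll|~10³).
  Monotone likelihood (a separating covariate) is reported as a
  `ConvergenceError` naming the covariate — detected both by a diverging
  coefficient and by an implausible linear-predictor spread
  (|beta|·range(x) > 100) at convergence, because with a finite sample the
  partial likelihood can flatten at a finite coefficient. Standard errors
  come from the inverse observed information; intervals are Wald with
  z = 1.96 fixed; HRs are per log2 unit, uncentered. The fitter is
  cross-checked in the tests against lifelines (Efron) and against a
  brute-force partial-likelihood grid oracle on small fixtures.
* **Baseline and adjusted curves**: Breslow cumulative hazard
  `H0(t) = Σ d_j / Σ_risk exp(x'β)`; an adjusted curve is
  `exp(−H0(t)·exp(x*'β))` with `x*` holding the within-half median of the
  displayed gene and the overall median of the other covariate (median
  split at ≤). Note `exp(−H0)` and the Kaplan–Meier product-limit curve
  agree only to second order in the per-time hazard increments; the test
  suite asserts 0.02 absolute agreement at n=150 rather than identity.
* **Meta-analysis**: fixed-effects inverse variance
  (`pooled = Σw_i b_i / Σw_i`, `w_i = 1/se_i²`,
  `pooled_se = (Σw_i)^(-1/2)`), cross-checked against statsmodels.
  Cochran's Q and I² are reported descriptively; random-effects pooling is
  out of scope.
* **Exact tests**: binomial and Fisher tests delegate to scipy
  (`binomtest`, `fisher_exact`), which implement the minimum-likelihood
  two-sided rule also used by R; both are verified against full
  enumeration oracles (all n ≤ 20 binomials; hypergeometric enumeration
  for 2×2 tables). The Wilcoxon rank-sum test uses exact enumeration for
  ≤ 12 pooled observations without ties, otherwise the tie-corrected
  normal approximation with continuity correction.

## Design choices where the procedure was genuinely open

* **TME quadrants**: only III (CD8A-low/PD-L1-high) and IV
  (CD8A-high/PD-L1-low) are fixed by usage; we name I = low/low and
  II = high/high as a documented convention. "Low" means ≤ median, which
  partitions odd and even cohorts cleanly and commutes with monotone
  per-gene transforms.
* **Portion pairing**: replicate columns sharing (patient, sample, portion)
  are averaged first — anything below the portion level is treated as a
  replicate. Tumors with more than two portions contribute one pair (the
  two lexicographically smallest portion codes), preserving independence
  across tumors for the binomial test. Pair orientation puts the
  higher-CD8A portion first; concordance counting is orientation-invariant.
  Zero deltas are excluded as ties rather than broken randomly.
* **Binomial sidedness**: one-sided by default — the reactive hypothesis
  pre-specifies the direction — with two-sided available; the printed
  concordance counts clear their significance bounds under either rule.
* **Matching**: greedy nearest-neighbor without replacement in increasing
  case-covariate order, ties broken lexicographically by sample id; a pair
  is dropped (control not consumed) when the best distance exceeds the
  caliper. Default caliper 0.1 log2 units of CD8A; controls default to
  copy-neutral (code 0) so deletions do not mix a second effect into the
  contrast. Optimal (Hungarian) matching is a non-goal.
* **Reactive efficiency**: PD-L1 is the regression response and the
  *signed vertical* residual is the score — the two sides of the line are
  meaningfully different (more vs less PD-L1 than the CTL level predicts),
  which an unsigned distance cannot express. Groups are residual tertiles,
  sizes (⌊n/3⌋, n−2⌊n/3⌋, ⌊n/3⌋), ties broken deterministically by sample
  id; explicit cutoffs can replace tertiles. The line is fitted within the
  scored cohort by default; a frozen line can be applied across cohorts.
  The outcome contrast uses the extreme groups only; the middle group's
  curve is reported separately.
* **Parameter recovery design**: univariate Cox recovery is only a
  well-posed oracle when the other hazard coefficient vanishes (otherwise
  the univariate fit targets a confounded marginal), so the recovery suite
  zeroes the other coefficient for univariate checks and uses the
  bivariate fit when both are active, with the latent CTL (stored in the
  cohort truth) as the covariate the hazard actually acts on.
* **Replicate-suite scenarios**: the immunotherapy reproduction runs at
  generator defaults; the adjustment sign-flip runs in the reactive regime
  (`frac_constitutive = 0`, single CNV state), because constitutive
  admixture — high PD-L1 uncorrelated with protective CTL — cancels the
  favorable marginal HR of PD-L1. That cancellation is itself a prediction
  of the adaptive-resistance account (cohorts with more constitutive
  expression show weaker favorable PD-L1 prognosis) and is directly
  observable by raising `frac_constitutive`.

## Problem sizes

The replicate suites use 100 seeds with cohorts of 500 (population), 300
(immunotherapy) and 11×120 (multi-cohort pooling, 50 seeds); together with
the enumeration oracles the full acceptance run computes in about a minute
on one CPU, and the test suite in about one minute. The power and
non-significance rates of the immunotherapy reproduction sit close to their
thresholds by design of the frozen conditions (analytic estimates ~0.8),
so their seed-to-seed fluctuation is a few percentage points.

## Known limitations

* Cox models are expression-only (no clinical covariates), with no
  time-varying effects, stratification, or proportionality diagnostics.
* The matching is single-covariate; propensity or multi-covariate matching
  is out of scope.
* The generator's Gaussian linear coupling cannot produce the heavy tails
  or zero inflation of real RNAseq; correlations are therefore cleaner
  than in real cohorts at the same parameter values.
* Immunohistochemistry-based analyses (staining quantification) and raw
  data acquisition/preprocessing (microarray RMA, GISTIC execution) are
  outside the package.
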