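# Methods note

Statistical conventions, estimators, and known limitations of the
`thrombomark` pipeline. Everything here is implemented and tested in the
package; no claim below goes beyond what the test suite computes.

## Design and matching

The pipeline analyzes a nested case-control study: VTE cases and non-VTE
controls are drawn from one cohort of advanced gastric cancer patients.
Patients under primary thromboprophylaxis are excluded before modelling
(`ClinicalCohort.exclude_thromboprophylaxis`); `fit_propensity` refuses
cohorts still containing them.

- **Propensity model.** Maximum-likelihood logistic regression of case status
  on the clinical covariates (statsmodels `Logit`). Perfectly separating
  covariates and zero-variance covariates are rejected with named errors
  rather than returning a saturated fit. Fitted propensities are clipped to
  (1e-12, 1 − 1e-12).
- **Matching.** Greedy 1:1 nearest-neighbor matching without replacement on
  the *logit* propensity scale. Cases are processed in descending propensity
  order (ties broken by input order); a control is eligible only within the
  caliper, `0.2 × SD(logit propensity)` by default (sample SD, ddof = 1).
  Cases with no eligible control are listed in `unmatched_cases`, never
  silently dropped.
- **Standardized difference.** For a binary covariate with case prevalence
  `p1` and control prevalence `p2`:

  `D* = 100 · (p2 − p1) / sqrt((p1(1 − p1) + p2(1 − p2)) / 2)`

  Note the **control-minus-case sign convention** — this is the convention
  that reproduces the published table the fixtures derive from. A continuous
  analogue (mean difference over the pooled SD) is used for age. |D*| < 10%
  is the conventional balance threshold. Zero-variance cells (p1 = p2 ∈
  {0, 1}) are an error, and zero-variance covariates in the post-matching
  balance table yield NaN rather than a division by zero.

## Differential expression

- **Test.** Per-gene two-sample Student *t* (pooled variance) of cases vs
  controls on log2 expression, vectorized across genes; Welch's form is
  available behind a flag. Genes with zero pooled variance are excluded from
  the results with a logged reason. Strata with fewer than two samples per
  group are rejected.
- **Fold change.** Signed convention: for a log2 mean difference `d`, the
  fold change is `2^d` when `d ≥ 0` and `−2^(−d)` otherwise, so |FC| ≥ 1
  always and the sign carries the direction. The transform is invertible
  (`delta_log2_from_fold_change`).
- **Multiplicity.** Benjamini–Hochberg step-up via statsmodels
  `multipletests(method="fdr_bh")`, cross-checked in the tests against a
  brute-force implementation.
- **Variance moderation (optional).** A limma-style empirical-Bayes step:
  the scaled-inverse-chi-square variance prior `(d0, s0²)` is estimated by
  method of moments on the log sample variances (trigamma inverse by Newton
  iteration), per-gene variances are squeezed toward `s0²`, and the *t*
  statistics are recomputed with `df + d0` degrees of freedom. Degenerate
  ensembles (equal variances, or `d0 = ∞`) reduce to a logged no-op /
  common-variance test. The moderation needs at least 10 genes.

## Concordance selection

A gene is selected only if, in **both** Lauren strata separately, it has
raw p < 0.05, BH-adjusted p < 0.10 and |FC| > 1 (all strict inequalities),
*and* the fold-change sign agrees between strata. Genes are labelled
`under`/`over` (expression in VTE vs controls) and returned in canonical
gene-symbol order, so the result is invariant to the stratum order.

## Conditional logistic regression

For a stratum of `m` subjects with `k` cases and exposures `x`, the
conditional likelihood of the observed case set given `k` is
`exp(β·Σ_cases x) / B(β)` with `B(β) = Σ_{k-subsets S} exp(β·Σ_S x)`.
Conditioning eliminates the stratum-specific intercepts, so the model is
adjusted for the stratifying variable (Lauren histology, or matched-pair id,
under which it reduces to the matched-pairs likelihood).

- `B`, `B′`, `B″` are evaluated by the exact two-index recursion over
  (subjects seen, cases used) in O(m·k) — never by subset enumeration. The
  tests verify equality with brute-force enumeration.
- Exposures are centered within each stratum before exponentiation (the
  likelihood is invariant to within-stratum shifts), keeping the recursion
  numerically safe.
- Newton–Raphson from β = 0 with step-halving; convergence at |score| < 1e-8
  or |step| < 1e-10, at most 50 iterations.
- **Separation.** If the observed case exposure sum attains the largest (or
  smallest) sum achievable by any k-subset in every stratum, the likelihood
  is monotone and the MLE sits at ±∞. This is detected *exactly* before
  fitting and reported as non-estimable (NaN estimate, `converged=False`)
  rather than as a huge odds ratio; |β| > 30 during iteration is a second,
  redundant guard. Strata with 0 or all cases contribute no information and
  are skipped with a log message.
- Wald standard errors from the observed information; 95% CIs as
  `exp(β ± 1.96·SE)`; constant-exposure fits return OR 1 with p = 1 and an
  undefined SE.

## Molecular subtyping

Per gene, quartiles are taken across samples with linear interpolation
(quantile type 7); a sample's value is an outlier if it lies strictly above
`Q3 + 1.5·IQR` ("high") or strictly below `Q1 − 1.5·IQR` ("low"). A subtype
signature's score for a sample is the fraction of its marker genes present in
the matrix whose flag matches the expected direction (up → high, down → low).
The sample is assigned the argmax-score subtype when the top score is
≥ `min_score` (default 0.25) and beats the runner-up by ≥ `margin` (default
0.05); ties therefore never resolve by subtype order. Otherwise the sample is
imputed from clinical features, in order: HER2-positive → CIN; diffuse
histology and age < 50 → GS; further rules are configurable. Samples failing
every rule fall back to histology (diffuse → GS, intestinal → CIN) and are
flagged `low_confidence`.

**Known limitation (by construction of the fence rule).** Tukey fences are
computed across the cohort, so a marker block can only be a *relative*
outlier when the subtype carrying it is rare. Once a subtype's prevalence
approaches the upper-quartile mass (~20–25%), the fence chases the shifted
block and the markers stop being flagged — larger shifts make this worse, not
better. Consequently, expression-rule recovery is validated on rare planted
subtypes (a few samples per subtype against an unclassifiable background),
and cohorts with common subtypes should expect a substantial imputed
fraction. This mirrors the behavior of the original criterion; it is not a
bug in this implementation.

## Per-subtype exploratory screen and annotation

Within each assigned subtype, the same Student-*t* machinery runs at
exploratory thresholds: raw p < 0.05 and |FC| > 1.5 with **no multiplicity
adjustment** — deliberately, as a hypothesis-generating screen. Subtypes with
fewer than 2 cases or 2 controls are skipped, logged and reported. Hits are
annotated by inner join against a **static local** gene →
Reactome-hemostasis-pathway table (shipped fixture, or any user TSV/GMT);
probe-level entries covering several genes (symbols separated by `;`) are
split so each constituent gene matches on its own row. No web service is
queried, for reproducibility.

## Synthetic-data generator

The generator produces data *shaped like* the study, for calibration and
testing — it makes no biological claims.

- **Cohort.** Binary clinical covariates are drawn independently per patient
  at the published pooled prevalences; age is uniform on 20–89; Lauren
  histology at the published mix. VTE is assigned by a logistic model whose
  covariate log-odds mirror the observed imbalance directions
  (confounding strengths 0.1–0.45, overridable) and whose intercept is solved
  numerically (Brent) so the expected event rate matches the published
  211/2129. Thromboprophylaxis is an independent flag at 6%. Covariate
  independence is a simplification: real clinical covariates are correlated;
  the generator makes no attempt to model that.
- **Expression.** Baseline log2 intensities are i.i.d. Normal(7.0, 0.5).
  Planted thrombosis genes shift VTE samples of the designated stratum by
  the signed log2 fold change; each subtype's marker genes shift its samples
  by `signature_shift` (default 1.5 = 3 baseline SDs) in the signed
  direction; designated "ambiguous" samples carry no signature. Gene-gene
  correlation is not modelled.
- All sizes (2129 patients, 2000 genes, 15 planted genes at the published
  per-stratum fold changes, 80-gene signatures) are **package defaults
  chosen to emulate the study scale**, not estimates; every one is
  overridable through `CohortSpec` / `ExpressionSpec`.

## Determinism

A single integer seed drives each generator (`numpy.random.default_rng`);
the pipeline derives its expression seed as `seed + 1`. Rerunning a pipeline
config reproduces byte-identical reports; the JSON manifest records seed,
thresholds, package version and per-stage counts and carries no timestamps.
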