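# thrombomark

Thrombosis-associated gene discovery in advanced gastric cancer via a nested
case-control design.

Venous thromboembolism (VTE) is a frequent, outcome-relevant complication of
advanced gastric adenocarcinoma, and no expression-based marker of VTE risk is
established. This package implements a complete analysis pipeline for finding
candidate thrombosis genes in a registry-scale cohort:

1. **Nested case-control construction** — VTE cases are matched 1:1 to
   non-VTE controls by propensity score (logistic model on clinical
   covariates; greedy nearest-neighbor matching without replacement on the
   logit scale, caliper 0.2 × SD of the logit propensity). Patients under
   primary thromboprophylaxis are excluded first. Balance is reported as
   standardized differences (D\*, in %), with |D\*| < 10% the conventional
   balance threshold.
2. **Stratified differential expression** — per-gene two-sample Student
   *t*-tests of VTE cases vs controls, run separately within the two Lauren
   histology strata (diffuse / intestinal), with signed fold changes,
   Benjamini–Hochberg adjustment, and an optional empirical-Bayes variance
   moderation step.
3. **Cross-stratum concordance selection** — a gene is a candidate only if it
   passes p < 0.05, BH-adjusted p < 0.10 and |FC| > 1 in *both* strata with
   the same fold-change direction.
4. **Conditional logistic regression** — a univariable conditional-logistic
   model per candidate gene, stratified by Lauren histology (or by matched
   pair), eliminates stratum-specific baseline risks without estimating
   per-stratum intercepts. The conditional likelihood denominator and its
   derivatives are computed by the exact O(m·k) recursion, never by subset
   enumeration.
5. **Molecular subtyping** — samples are classified into the four gastric
   molecular subtypes (EBV, MSI, GS, CIN) from marker-gene signatures using
   Tukey-fence relative outliers (above Q3 + 1.5·IQR / below Q1 − 1.5·IQR per
   gene across samples); unclassifiable samples are imputed from clinical
   features (HER2-positive → CIN; young diffuse-histology → GS).
6. **Per-subtype exploratory screen** — within each molecular subtype, an
   unadjusted screen (p < 0.05, |FC| > 1.5) followed by annotation against a
   static local gene → Reactome-hemostasis-pathway table.

Because the underlying expression data of such studies are typically not
deposited, the package ships a **synthetic-data generator** that emulates the
cohort structure the analysis assumes (registry-scale covariate prevalences,
confounded VTE assignment at the published event rate, planted per-stratum
fold changes and subtype marker blocks), so every stage can be exercised,
calibrated, and tested end to end. Published summary tables are shipped as
plain-text fixtures for the deterministic consistency checks.

## Worked example

Run the full pipeline on synthetic study-scale data (~2100 patients, 2000
genes; a few seconds on one CPU):

```python
from thrombomark import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7, output_dir="results/run7")
manifest = run_pipeline(config)

m = manifest["stages"]["matching"]
print(f"matched pairs: {m['n_pairs']} (unmatched cases: {m['n_unmatched_cases']})")
print(f"mean |D*| before -> after: {m['mean_abs_dstar_before']:.1f}% -> {m['mean_abs_dstar_after']:.1f}%")
s = manifest["stages"]["dge_selection"]
print(f"concordant genes: {s['n_selected']} ({s['n_under']} under-, {s['n_over']} overexpressed)")
c = manifest["stages"]["clogit"]
print(f"conditional-logistic fits: {c['n_fits']}, CI excluding OR=1: {c['n_ci_excluding_1']}")
print(f"subtype counts: {manifest['stages']['subtyping']['counts']}")
```

Output:

```text
matched pairs: 198 (unmatched cases: 0)
mean |D*| before -> after: 13.1% -> 6.8%
concordant genes: 4 (1 under-, 3 overexpressed)
conditional-logistic fits: 4, CI excluding OR=1: 4
subtype counts: {'CIN': 247, 'EBV': 4, 'GS': 131, 'MSI': 14}
```

`results/run7/` then contains the per-stage reports (`balance_table.tsv`,
`matched_pairs.tsv`, `dge_{diffuse,intestinal}.tsv`, `concordant_genes.tsv`,
`clogit.tsv`, `subtype_assignments.csv`, `hemostasis_<subtype>.tsv`) and a
`manifest.json` recording seed, thresholds and per-stage counts. Reruns with
the same config are byte-identical. The top of `clogit.tsv` from the run
above:

```text
# stage=clogit strata=lauren
gene_symbol	p_value	odds_ratio	ci_low	ci_high
CDC45	4.896e-07	2.820	1.883	4.225
PRKD3	3.748e-08	3.243	2.133	4.931
SDCBP	6.261e-15	6.288	3.961	9.982
```

The building blocks are usable directly:

```python
>>> from thrombomark import standardized_difference, signed_fold_change, clogit_fit
>>> standardized_difference(0.750, 0.694)   # case vs control prevalence, in %
-12.524109953695122
>>> signed_fold_change(1.45)                # log2 difference -> signed FC
2.732080513508791
>>> import numpy as np
>>> fit = clogit_fit(
...     x=np.array([1.2, 0.3, -0.5, 0.8, 2.0, -1.0, 0.1, 0.6]),
...     case=np.array([1, 1, 0, 0, 1, 0, 0, 0], bool),
...     strata=np.array(["diffuse"] * 4 + ["intestinal"] * 4),
... )
>>> print(f"OR {fit.odds_ratio:.2f} (95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), p = {fit.p_value:.3f}")
OR 6.36 (95% CI 0.37-110.53), p = 0.204
```

### Command line

Every stage is also a `thrombomark` subcommand:

```bash
thrombomark simulate --seed 7 --cohort-out cohort.csv --expression-out expr.tsv
thrombomark match --cohort cohort.csv --pairs-out pairs.tsv --balance-out balance.tsv
thrombomark dge --expression expr.tsv --cohort cohort.csv --stratum diffuse --out de_d.tsv
thrombomark dge --expression expr.tsv --cohort cohort.csv --stratum intestinal --out de_i.tsv
thrombomark select --de-a de_d.tsv --de-b de_i.tsv --out selected.tsv
thrombomark clogit --expression expr.tsv --cohort cohort.csv --genes GENE1,GENE2 --out or.tsv
thrombomark run --seed 7 --output-dir results/run7     # full pipeline
```

## Package layout

| Module | Contents |
| --- | --- |
| `thrombomark.synthetic` | cohort and expression generators (`CohortSpec`, `ExpressionSpec`) |
| `thrombomark.matching` | propensity model, greedy caliper matching, D\* balance reports |
| `thrombomark.dge` | Student/Welch *t* screen, signed fold changes, BH, eBayes moderation |
| `thrombomark.selection` | cross-stratum concordance rule |
| `thrombomark.clogit` | conditional logistic regression (exact recursion + Newton) |
| `thrombomark.subtyping` | Tukey-fence outlier flags, signature scores, subtype assignment |
| `thrombomark.pathways` | per-subtype exploratory screen, hemostasis annotation |
| `thrombomark.io`, `thrombomark.cli`, `thrombomark.pipeline` | file formats, CLI, orchestration |

Statistical conventions, estimator details, generator assumptions and known
method limitations are documented in [docs/methods.md](docs/methods.md).

## Reproduction

All tests, including the acceptance suite (`tests/test_acceptance.py`, one
test per acceptance criterion — fixture-exact recomputations plus oracle,
recovery, calibration and balance property checks):

```bash
pytest -q
```

The deterministic acceptance-target values (standardized differences from the
published balance percentages and the concordant-gene count from the published
per-stratum screens) are computed at runtime by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Both complete in a few minutes on a single CPU with no network access.
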