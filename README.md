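# prediarem

Metabolic phenotyping and progression analysis for prediabetes-remission
studies, built around the oral glucose tolerance test (OGTT).

Lifestyle-intervention trials in prediabetes traditionally judge success by
weight loss.  A complementary question is whether participants return to
**normal glucose regulation** (NGR: fasting glucose < 5.6 mmol/l, 2-h
post-load glucose < 7.8 mmol/l, HbA1c < 39 mmol/mol) even when they do not
lose weight — and whether that remission protects against type 2 diabetes.
Answering it requires a chain of standard but fiddly computations:
OGTT-derived indices of insulin sensitivity and secretion, kinetic
deconvolution of C-peptide into a prehepatic insulin secretion rate,
ADA-based glycemic classification, a visceral-fat polygenic score with
genotype quality control, and a longitudinal/survival statistics layer.
`prediarem` implements this chain as a tested, reusable pipeline for
biostatisticians and clinical researchers, together with a synthetic cohort
generator that emulates the structure of such a trial so every stage can be
exercised without access-restricted patient data.

## What it computes

**OGTT index panel** (`prediarem.ogtt`), per subject-visit from glucose,
insulin and C-peptide sampled at 0/30/60/90/120 min after a 75 g load:

- OGIS (oral glucose insulin sensitivity, ml·min⁻¹·m⁻², 120-min closed
  form), Matsuda composite index
  `10000 / √(G₀·I₀·Ḡ·Ī)`,
- hepatic insulin resistance `AUC_G(0–30) × AUC_I(0–30)`, muscle insulin
  sensitivity (post-peak glucose decay rate / mean insulin), adipose
  insulin resistance (fasting NEFA × fasting insulin),
- early-phase secretion `AUC_Cpep(0–30) / AUC_gluc(0–30)` (pmol/mmol), the
  adaptation index `secretion × OGIS` (a disposition-index analogue), and
  hepatic insulin clearance `AUC_Cpep(0–120) / AUC_ins(0–120)`.

**Insulin secretion rate** (`prediarem.cpeptide`): two-compartment
C-peptide kinetics with population (Van Cauter-type) parameters; exact
matrix-exponential forward simulation; non-negative, smoothness-regularized
deconvolution of sampled C-peptide into ISR (pmol/min); β-cell–GLP-1
sensitivity as paired incremental AUCs; glucagon suppression.

**Classification** (`prediarem.classify`): NGR / prediabetes / T2D
partition (standard 2-h or the 1-h 155 mg/dl variant), responder labelling
at month 12, the non-weight-loss stratum filter (Δweight ≥ 0), transition
tables.

**Polygenic score** (`prediarem.prs`): SNP QC (missingness > 5 %, MAF < 1 %,
exact Hardy–Weinberg test p < 0.05), allele harmonization, weighted dosage
score and covariate residualization.

**Statistics** (`prediarem.stats`): linear mixed models of
`outcome ~ group × time + covariates` with a random intercept per subject
(REML, via statsmodels), Benjamini–Hochberg correction across the model
family, Holm-corrected within-group changes, risk ratios with log-method
CIs plus Fisher's exact test, in-package Kaplan–Meier and log-rank
(cross-checked against lifelines), Wilson intervals for stratified
remission rates, and chained-equation multiple imputation for imaging
variables.

**Synthetic cohorts** (`prediarem.simulate`): 51 responders / 183
nonresponders by default, with group×visit curve shapes, correlated fat
depots, genotypes with known-truth QC failures, and exponential
time-to-diabetes calibrated so the responder risk ratio is ≈ 0.29.

## Worked example

```sh
prediarem simulate --seed 0 --out cohort/
prediarem analyze --in cohort/ --out report/ --seed 0
```

or in Python:

```python
import prediarem as pr

cohort = pr.generate_cohort(pr.default_config(), seed=0)
cohort.write("cohort")
report = pr.run_pipeline("cohort", out_dir="report", seed=0)

print(report["cohort"])
ogis = next(m for m in report["models"] if m["outcome"] == "ogis")
print(f"OGIS change R {ogis['change_R']:.1f}, NR {ogis['change_NR']:.1f}, "
      f"interaction p {ogis['p_interaction']:.2g}")
print(f"risk ratio {report['progression']['relative_risk']:.2f}")
```

prints

```
{'n_non_weight_loss': 234, 'n_responders': 51, 'n_nonresponders': 183, 'pct_responders': 21.8, 'pct_nonresponders': 78.2}
OGIS change R 68.3, NR -2.9, interaction p 4.6e-59
risk ratio 0.44
```

Reading: of the 234 simulated non-weight-loss subjects, the 51 responders
(21.8 %) gain ~68 ml·min⁻¹·m⁻² of OGIS insulin sensitivity over the
intervention while nonresponders stay flat (a strongly significant
group × time interaction), and responders carry less than half the
nonresponders' diabetes risk over follow-up (at this cohort size the point
estimate is noisy around the calibrated 0.29; the acceptance script below
recomputes it at a sample size where it stabilizes).

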