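# Methods

This note documents the models, numerical choices and limitations behind
`prediarem`.  It is written for a reader who wants to know exactly what the
package computes and what passing its tests does and does not demonstrate.

## OGTT index panel

All indices operate on glucose (mmol/l), insulin and C-peptide (pmol/l)
sampled at 0/30/60/90/120 min after a 75 g oral glucose load.  Formulas
defined in the clinical unit system convert internally with a glucose molar
mass of 180.156 g/mol (so 100 mg/dl = 5.55 mmol/l) and an insulin factor of
6.0 pmol/l per µU/ml.  The insulin factor is a convention, not a physical
constant; `UnitSystem(insulin_pmol_per_uU=6.945)` switches to the WHO
alternative.  All areas under curves use the trapezoidal rule on the sampled
grid; window endpoints must be sampled times and no interpolation is ever
performed — a missing 30-min sample makes the affected index missing rather
than silently interpolated.

**OGIS (120-min variant).**  The closed-form expression

    cl   = p4 * ((p1*D - V*(G120 - G90)/30) / G90 + p3/G0) / (I90 - I0 + p2)
    OGIS = (cl + sqrt(cl^2 + 4*p5*p6*(G90 - Gcl)*cl)) / 2

with glucose in mg/dl, insulin in µU/ml, dose D in g per m² of DuBois body
surface area, distribution volume V = 10⁴ ml/m² and clamp reference
Gcl = 90 mg/dl; the regression constants are the published 2-h protocol set
p = (289, 270, 14·10³, 440, 637·10⁻⁶, 117).  The implementation is verified
in the test suite against an independently written plain-arithmetic
transcription of the same expression on a frozen reference profile (the
original web calculator cannot be queried from an offline test run, so the
oracle guards against transcription and unit-conversion slips rather than
against an independent source).  Only the 2-h variant is implemented;
records without 90- and 120-min samples raise.

**Muscle insulin sensitivity.**  Defined as the rate of glucose decline
from the OGTT glucose peak to the subsequent minimum (least-squares slope
over that span, entered as a positive decay rate, mg/dl/min) divided by the
mean insulin concentration (µU/ml).  When glucose rises monotonically there
is no decline phase and the index is reported missing (NaN), not as an
error: such curves are legitimate in severe dysglycemia.

**Hepatic insulin resistance** uses the 0–30 min AUC product
(glucose × insulin); the early window matches the other early-phase
computations in the panel.  **Adipose insulin resistance** is fasting NEFA
(mmol/l) × fasting insulin (µU/ml); NEFA is typically measured in a
subgroup, and a missing NEFA propagates as a missing index.  The
**adaptation index** is the exact product of the early-phase secretion
index (C-peptide AUC₀₋₃₀ / glucose AUC₀₋₃₀, pmol/mmol) and OGIS; the
identity `adaptation = secretion × OGIS` is asserted for every computed
panel.

## C-peptide kinetics and secretion-rate estimation

Plasma C-peptide follows a linear two-compartment model with elimination
from the accessible compartment:

    dC1/dt = ISR/V - (k01 + k12) C1 + k21 C2
    dC2/dt = k12 C1 - k21 C2

Population parameters are the anthropometry-based scheme used by the
standard deconvolution programs: the impulse response is a double
exponential with fast fraction F and fast/slow half-lives by metabolic
class — (0.76, 4.95, 29.2 min) for lean normal glucose tolerance,
(0.78, 4.55, 33.1) for obesity, (0.78, 4.52, 26.9) for type 2 diabetes —
and V = 1.92·BSA + 0.64 litres.  Subjects with prediabetes use the obese
class (the cohorts this targets have mean BMI ≈ 30).  These constants are
pinned in one table; every downstream result that matters (round-trip
recovery, the ratio-type indices) is insensitive to their exact values
because the same parameters are used in both the forward and the inverse
direction.  Rate constants derive from the eigenvalue relations
λ₁+λ₂ = k01+k12+k21, λ₁λ₂ = k01·k21, k01+k12 = Fλ₁+(1−F)λ₂, and the
rates-to-half-lives round trip is asserted in tests.

**Forward simulation** treats ISR as piecewise linear between sampling
knots and propagates the augmented state (C1, C2, u, du/dt) with one 4×4
matrix exponential per interval — exact for this input class, so no
integration-step artifacts can leak into the deconvolution.  The peripheral
compartment starts at its steady-state ratio C2(0) = C1(0)·k12/k21.

**Deconvolution** estimates ISR at the sampling knots by non-negative least
squares on the exact forward map plus a second-difference (Tikhonov)
smoothness penalty λ.  The fasting sample is tied to the fasting secretion
knot through the steady state C1(0) = ISR(0)/(V·k01).  λ is chosen by the
discrepancy principle: the largest value on a 49-point geometric grid
(10⁻⁶…10⁶) whose data misfit stays within the noise level implied by the
assumed assay coefficient of variation (default 4 %).  The CV is a
parameter: for noise-free synthetic data the right setting is
`rule="fixed"` with λ = 0 (the problem is then exactly determined and the
round trip recovers smooth profiles to machine precision), and when the
noise level is known — as for the synthetic cohort, generated with 2 % CV —
the discrepancy rule should be given that CV.  With a mismatched, too-large
CV the rule deliberately over-smooths; this is the usual bias-variance
trade of regularized deconvolution, not a defect.

**β-cell–GLP-1 sensitivity** is reported as the pair of 0–30 min
incremental AUCs (ISR and GLP-1) plus their ratio; the ratio is flagged
missing when the GLP-1 increment is non-positive.  The underlying analysis
plots the two increments against each other without naming a scalar, so the
ratio is the minimal faithful summary and both components are always
emitted alongside.  Because the reported ISR-AUC quantity in this
literature does not always state its window, both the 0–30 and 0–120 min
areas are exposed (`ISRProfile.iauc`, `ISRProfile.auc`).

## Glycemic classification

NGR requires all of: fasting glucose < 5.6 mmol/l, post-load criterion
(2-h < 7.8 mmol/l, or 1-h < 8.6 mmol/l [155 mg/dl] in `one_hour` mode),
HbA1c < 39 mmol/mol — all comparisons strict.  T2D requires any of fasting
≥ 7.0, 2-h ≥ 11.1, HbA1c ≥ 48 (inclusive); the remainder is prediabetes.
The diabetes-side thresholds complete the partition with the standard ADA
diagnostic values.  In `one_hour` mode the 1-h cutoff *replaces* the 2-h
NGR criterion rather than adding to it, while the T2D side still uses the
2-h diagnostic threshold when a 2-h value exists.  A responder is a subject
whose month-12 visit classifies as NGR; labels are defined only inside the
non-weight-loss stratum, `weight12 − weight0 ≥ 0` (exact weight maintenance
included — "did not lose").  HbA1c conversion uses the NGSP/IFCC master
equation NGSP(%) = 0.09148·IFCC + 2.152.

## Polygenic score

QC drops SNPs with missingness > 5 %, minor allele frequency < 1 % or an
exact conditional Hardy–Weinberg test p < 0.05; the HWE test runs on
hard-called (rounded) dosages, sums heterozygote configurations no more
probable than the observed one, and is verified against full enumeration.
The exact test at small counts is the standard QC choice; a chi-square
variant is deliberately not the default.  Scores are weighted effect-allele
dosage sums over retained SNPs; weights stated for the other allele are
applied to the reflected dosage 2−d, strand-ambiguous A/T and C/G SNPs
raise rather than guess, and missing dosages are mean-imputed per SNP
(configurable: drop subject, or zero).  A published 205-SNP predicted-VAT
panel reducing to 186 after QC is reproduced by the rules themselves on the
user's genotypes, not by a hard-coded exclusion list.  Adjustment
residualizes the score on age, sex and BMI by OLS — the covariate set
mirrors the main longitudinal models, since the original adjustment set is
not spelled out.

## Statistics layer

Longitudinal outcomes use linear mixed models, `value ~ group × time +
age + sex + BMI(baseline) + risk stratum + intervention intensity`, random
intercept per subject, REML, fitted by statsmodels; the secretion models
additionally adjust for concurrent insulin sensitivity (OGIS).  Baseline
BMI is used as the covariate because time-varying BMI would absorb the
exposure of interest.  Inference on the interaction contrast uses the
large-sample normal approximation to the Wald statistic (recorded in every
result object); at the design sizes here this is equivalent to the exact
paired-contrast t-test to within a few thousandths, and the type-I error
is verified by simulation in the test suite.  Within-group baseline→12-month
changes are contrasts of the same fit, Holm-corrected as a family of two;
interaction p-values are Benjamini–Hochberg-corrected across the model
family (step-up, implemented in-package and verified against the
definitional brute force).

Progression analysis: risk ratio from the 2×2 event table with the
log-method CI, exp(ln RR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), and
Fisher's exact p alongside; Kaplan–Meier product-limit curves and the
two-group log-rank test (hypergeometric variance form) are implemented
in-package and cross-checked against lifelines to 10⁻⁸ — the library serves
as the independent oracle, never as the implementation.  Stratified
remission proportions carry 95 % Wilson score intervals (the CI method is a
package choice; bins follow the half-open [lo, hi) convention).  Missing
imaging variables (liver fat, SCAT, VAT) are completed by chained-equation
multiple imputation (statsmodels MICE, predictive mean matching, m = 5,
seeded); per-imputation estimates combine by Rubin's rules.

Intervention intensity is modelled as a three-level categorical covariate
(control / conventional / intensified); pooling control with conventional
is a documented alternative the data tables support but the default does
not apply.

## Synthetic cohort generator

The generator emulates the structure of a non-weight-loss stratum of a
prediabetes lifestyle-intervention trial: 51 responders and 183
nonresponders by default, followed for 10 years.  Group × visit means are
calibrated to published cohort summaries; dispersions quoted as 95 % CIs of
means are converted to SDs as `ci_half_width · √n / 1.96`.  Baseline and
month-12 values of each continuous phenotype are bivariate normal with
within-subject correlation ρ = 0.7.  SCAT and VAT are drawn *jointly* with
a cross-sectional correlation of 0.5 (depot volumes co-vary with overall
adiposity); without it the SCAT/VAT ratio — whose published trajectory the
generator is calibrated against — would be dominated by small-denominator
noise and far more dispersed than real imaging data.  Physiological floors
(1 l VAT, 3 l SCAT, small positive floors elsewhere) are applied by
clipping, not rejection: rejection of joint draws would shift every
correlated margin upward, while clipping keeps the realized means within
the Monte-Carlo tolerance of the configured targets.

OGTT curves are generated as group × visit mean profiles plus a
subject-level fasting shift (glucose, additive, SD 0.4 mmol/l), a
subject-level log-normal insulin factor and per-point noise.  HbA1c is
linked linearly to fasting glucose (6 mmol/mol per mmol/l around the
39/5.6 anchor, SD 1.5) so that remission requires all three criteria to
co-move.  C-peptide is never sampled directly: each subject-visit draws a
secretion-rate profile (basal rate tied to fasting C-peptide through the
kinetic steady state, plus a scaled early bump peaking at 30 min), pushes
it through the forward two-compartment model and adds 2 % multiplicative
assay noise — so deconvolution always has a ground truth.  Visits are
rejection-sampled to satisfy the design's glycemic constraints (baseline
prediabetes everywhere; month-12 NGR for responders, non-NGR for
nonresponders); when a subject's fasting shift makes a required status
unreachable the shift itself is redrawn, and a configuration whose curve
means conflict with the thresholds raises rather than looping.

Event times are exponential with the rate solved from the configured
10-year cumulative incidence per group (0.0725 responders, 0.25
nonresponders, giving a true risk ratio of 0.29); censoring is uniform on
the follow-up window for a configurable fraction (default 15 %), with
administrative censoring at the horizon otherwise.  Genotypes are binomial
effect-allele dosages at uniform MAFs with injected, truth-labelled QC
failures (7 high-missingness, 6 near-monomorphic, 6 with strong excess
homozygosity out of 205 SNPs by default) and ~10 % of weights stated for
the opposite allele to exercise harmonization.

**What the generator does not emulate.**  Curves are noise around fixed
shapes, not a physiological glucose-insulin control loop; indices computed
from them land at realistic magnitudes but are not forced to reproduce any
particular published index mean (the printed group summaries act as
calibration inputs for the drawn quantities, and some published index
summaries are not jointly reachable from a single consistent curve set —
e.g. a Matsuda index near 9 and an AUC-ratio clearance near 3.9 imply
different insulin scales).  Missingness patterns, assay batch effects,
center effects and any specific trial's full covariance structure are not
modelled.  Passing the end-to-end tests therefore demonstrates that the
pipeline recovers the qualitative group × time pattern (sensitivity and
secretion improving in responders only, visceral fat rising in
nonresponders only, SCAT/VAT ratio rising in responders) and the
calibrated progression risk ratio from data with this structure — not that
it reproduces any restricted-access dataset's numbers.  At the default
n = 51/183 the ratio outcome in particular retains appreciable seed-level
noise; the sign pattern is asserted at a fixed seed.

## Problem sizes and determinism

The test suite simulates at the sizes its questions need and no larger:
type-I error of the mixed-model interaction with 1,000 null replicates at
n = 30/group; risk-ratio CI coverage with 1,000 replicates at n = 600/group;
secretion round trips over 100 random smooth profiles; KM/log-rank
equivalence over 100 random censored datasets; the end-to-end pattern on
one default cohort (234 subjects).  The acceptance script simulates 200,000
subjects per group, where the binomial noise on the risk ratio is ±0.003.
All randomness flows through `numpy.random.default_rng` seeds; cohorts and
reports are byte-reproducible for a given seed.
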