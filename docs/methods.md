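# Methods

`lipidscan` implements the statistical analysis path used by large
two-cohort plasma lipidomic studies of Alzheimer's disease (AD): per-lipid
association scanning for prevalent diagnosis and incident conversion,
cross-cohort fixed-effects meta-analysis, correlation clustering of the
lipid panel, and cluster-aware multivariate risk-model building with
cross-cohort replication. A synthetic two-cohort generator with planted
ground truth stands in for individual-level study data, so every stage is
testable end to end.

## Lipid nomenclature and class totals

Species names follow the Lipid Maps / Liebisch shorthand,
`CLASS(prefix-chain[/chain][_chain]) [tags]`. The parser records:

* ether linkage — `O-` (alkyl) and `P-` (alkenyl/plasmalogen) prefixes on
  the first chain, which move the species into the `CLASS(O)` / `CLASS(P)`
  subclass. Plasmalogen chains contribute only their printed double bonds;
  the vinyl-ether bond is not added to the total.
* sphingoid bases (`d`/`t` prefixes) vs n-acyl chains;
* `/` (known sn positions) vs `_` (unknown) chain separators;
* chromatographic isomer labels `(a)`/`(b)`, lyso-species position tags
  `[sn1]`, neutral-loss tags `[NL-16:0]`, and methyl-branch tags such as
  `15-MHDA` (methylhexadecanoic acid, a branched 16:0).

A name with fewer chain tokens than the class's full complement (e.g.
`SM(43:1)`, `TG(O-52:2)`) is a sum composition: totals are recorded and
the chain list left empty. Parsing then canonical serialisation is the
identity on every supported name; this round-trip is enforced in tests on
the full synthetic panel and on a catalogue of published species names.

The species → class taxonomy is configuration (a two-column registry
file), not code: panels differ between laboratories. Class totals are
arithmetic sums of member species on the raw concentration scale — sums of
log-transformed values would not be concentrations — computed after batch
alignment and before the log transform.

## Preprocessing

**Batch alignment.** Targeted lipidomics runs in analytical batches with
pooled plasma QC samples embedded in each. Per-lipid batch drift is
multiplicative, so each lipid in each batch is rescaled by
(panel-wide QC median)/(batch QC median). After alignment the per-batch QC
medians agree exactly across batches for every lipid (asserted to 1e-10 in
tests). Multiplicative correction on the raw scale equals an additive
shift in log space and preserves relative scale. Batches without QC
samples, and zero QC medians, are errors.

**Transformation.** Plasma lipid concentrations are positively skewed;
analyses use log10 concentrations z-scored per cohort using the mean and
SD of the rows included in the given analysis only, so excluded rows can
never leak into the scaling. Effects are therefore "per SD of log10
concentration", and exp(beta) is an odds or hazard ratio per SD.

**Analysis sets.** The *prevalent* set takes each participant's last
acquired sample, excludes MCI (clean AD vs CN contrast), and encodes
timepoint as categorical indicators when several timepoints exist. The
*incident* set takes baseline samples only, excludes prevalent AD, retains
MCI (with an indicator available for sensitivity adjustment), and encodes
the outcome as (entry age, exit age = age + follow-up, converted) for
age-as-timescale Cox models. Missing covariates are handled by
complete-case deletion with a logged count; duplicate aliquots at one
timepoint keep the first-read row with a warning. No imputation and no
outlier-sample heuristics are applied.

## Per-lipid association models

* **Prevalent:** logistic regression of AD vs CN on one standardized lipid
  plus covariates (age, sex, BMI, total cholesterol, HDL-C,
  triglycerides, APOE ε4 count, statin, omega-3; plus site/timepoint or
  fasting indicators where the cohort design has them). Wald two-sided
  p-values. Fits with complete or quasi-complete separation are flagged
  (p = NaN) rather than raised, and excluded from the FDR family.
* **Incident:** Cox partial likelihood with age as the timescale — entry
  at baseline age (left truncation), exit at conversion/censoring age —
  Efron tie handling, same covariates except age (it is the timescale).
  Fits are delegated to lifelines.
* **FDR:** Benjamini–Hochberg step-up within the species family and the
  class family separately. The family size may exceed the number of
  testable lipids; the implementation takes it as an explicit argument and
  matches `statsmodels.multipletests` exactly when family = length.
* **Group tests for cohort tables:** a two-group one-way ANOVA
  reconstructed from (n, mean, SD) summaries (equals the squared pooled
  t statistic) and Pearson's chi-square without continuity correction.

Wald rather than likelihood-ratio p-values are used throughout: they are
the standard output of both model families and uniform across cohorts.

## Meta-analysis

Inverse-variance fixed-effects pooling: w_i = 1/se_i², beta = Σw_iβ_i/Σw_i,
se = (Σw_i)^(-1/2), z = beta/se, p = 2Φ(−|z|), with BH FDR re-applied per
family on the pooled p-values. Flagged cohort fits are dropped before
pooling; a lipid usable in a single cohort passes through flagged
`single_study`. Two-sided normal p-values without small-sample t
correction, per meta-analysis convention; heterogeneity statistics (Q, I²)
are deliberately not computed — the pooling model is fixed-effects only.

## Correlation clustering

Panels are strongly co-linear. Clustering uses Spearman correlation
(monotone-invariant, so the raw/log scale choice is irrelevant), signed
distance d = 1 − ρ (anti-correlated lipids must not share a cluster:
representatives must be positively interchangeable proxies), complete
linkage, and a dynamic hybrid tree cut:

1. *Branch detection.* The dendrogram is walked top-down. A branch is kept
   as a cluster when it has at least `min_cluster_size` members, its mean
   within-branch distance is below a core-scatter ceiling, and it does not
   contain a well-separated sub-branch (a child of at least minimum size
   whose merge-height gap from the parent exceeds a minimum gap). The
   ceiling and gap derive from `deep_split` (0–4) exactly as in the
   published dynamic-hybrid parameterisation: max core scatter ∈
   {0.64, 0.73, 0.82, 0.91, 0.95} of the cut height (0.99 × top merge
   height) and min gap = (1 − max core scatter) × 3/4.
2. *Singleton assignment.* Leftover lipids join the nearest detected
   cluster when their average distance to its members is below the height
   at which that cluster merges into the rest of the tree; otherwise they
   stay unassigned (label 0).

Clusters are relabelled 1..K by decreasing size. Defaults are
`min_cluster_size = 2`, `deep_split = 1`: published panels of ~570 species
yield ~150 clusters (average size < 4), so the minimum size must be
permissive. The implementation follows the algorithmic contract, not any
specific external implementation byte-for-byte; tests verify exact
planted-block recovery (ARI ≥ 0.95 over 20 seeds at within-block ρ = 0.8),
no clusters on independent panels, and co-clustering of duplicated
columns. Clustering is computed per cohort on its own standardized matrix.

## Risk models

**Base model.** Age, sex, BMI, APOE ε4 count (age enters Cox models as the
timescale instead of as a regressor).

**Matching.** Incidence discovery in a low-conversion cohort with a large
converter/non-converter age gap uses a 2:1 age–sex-matched baseline
subset: cases processed in descending age, each taking its two
nearest-age same-sex non-converters without replacement.

**Discovery.** Outcome-stratified 10-fold CV, repeated (default 10
repeats, so frequencies are out of 100 training fits — repetition
stabilises the ranking; a single pass is available by config). Within each
training fold, forward stepwise selection adds the lipid with the largest
AIC decrease (AIC = 2k − 2·loglik; partial likelihood for Cox), stopping
at the cap (10 lipids logistic, 5 Cox) or when no candidate lowers AIC.
Non-converged candidate fits are skipped. Correlated lipids substitute for
each other across folds and dilute their individual counts, so
frequencies are summed within clusters, clusters ranked by that sum, and
each cluster represented by its most-incorporated member; the top
representatives (frequency > 0 only) form the feature list. Frequency
ties between clusters break by the best (lowest) supplied AIC-rank score,
then lexicographically.

**Replication.** The replication cohort re-estimates all coefficients
from scratch (cohort case-mixes differ too much to transfer coefficients)
inside a fresh stratified 10-fold CV: per repeat, base and base+lipids
models are trained on each training portion, out-of-fold linear predictors
pooled, and the C-statistic and continuous NRI computed on the pooled
scores. Point estimates are means over 200 repeats, CIs the 2.5/97.5
percentiles over repeats (the published CI construction is unstated;
percentile-over-repeats is the natural choice given "calculated after 200
repeats"). Incidence models include MCI participants without an MCI
covariate, so the lipid markers' predictive value is assessed undiluted.

**Metrics.** Binary C-statistic = AUC with ties counted ½; survival
C-statistic = Harrell's C restricted to comparable pairs under left
truncation (the earlier event time must fall inside the other subject's
at-risk interval). NRI is the category-free (continuous) flavour — no risk
categories are defined anywhere in the modelling, so the threshold-free
definition is the only parameter-free choice: event component
P(up|event) − P(down|event), nonevent component P(down|nonevent) −
P(up|nonevent), total = sum; exact ties contribute zero. Both are verified
against exhaustive pair-counting oracles up to n = 200.

For speed, the stepwise and replication inner loops use an in-house Newton
solver for the logistic and Cox (Efron, left-truncated) log-likelihoods,
vectorised over event times by suffix sums; it is validated against
statsmodels and lifelines to ~1e-6 in the test suite. The public
per-lipid scan API stays on statsmodels/lifelines.

## Synthetic cohorts

The generator emulates the structure of an AIBL-like longitudinal plasma
cohort and an ADNI-like baseline serum cohort:

* **Panel:** default 8 classes × 25 species = 200 species (desk scale;
  full-size panels by config), named in valid shorthand.
* **Concentrations:** log10 values are multivariate normal with a block
  correlation structure — within-class correlation ρ_in (default 0.5)
  over a cohort-wide background ρ_out (default 0.1); the factor
  construction requires 0 ≤ ρ_out ≤ ρ_in < 1, which guarantees positive
  semi-definiteness (violations raise with the offending parameters).
  Per-species abundance means and SDs are drawn once per panel.
* **Batches:** consecutive blocks of 120 samples, 4 pooled-QC rows each;
  every row in a batch is multiplied by a per-lipid log-normal factor
  (SD 0.1 on log10 — realistic drift that QC-median alignment must remove
  exactly in expectation). QC rows are pool-mean draws with small
  technical noise (SD 0.02 log10).
* **Covariates:** age ~ N(75, 6.9²), ~57% female, BMI, cholesterol,
  HDL-C, log-normal triglycerides, APOE ε4 counts (62/31/7%), statin,
  omega-3, plus site (AIBL-like) or fasting (ADNI-like) design covariates.
* **Prevalent diagnosis:** Bernoulli from a logistic model on the planted
  standardized species effects plus age/APOE/sex effects; the intercept is
  calibrated by root-finding so the implied prevalence matches the
  configured CN/MCI/AD weights (defaults near the 7:1:2.5 mix of an
  AIBL-like cohort; the ADNI-like default is MCI-heavy, 30/45/25).
* **MCI:** among non-AD participants, the probability of an MCI label is
  logistic in the standardized incident risk score, calibrated to the MCI
  weight — MCI enriches among future converters without deterministically
  absorbing every high-risk participant (a hard top-band would, e.g.,
  strip APOE ε4 carriers out of the prevalent CN stratum and induce
  separation).
* **Incident conversion:** exponential baseline hazard on the age scale
  (default 0.02/yr AIBL-like, 0.10/yr ADNI-like) times exp(planted
  effects + covariate effects); entry at baseline age (memorylessness
  makes left truncation exact), administrative censoring at a uniform
  4–9 y (AIBL-like) or 1.5–3.5 y (ADNI-like) horizon.
* **Determinism:** one `numpy` generator seeded from the config; identical
  configs give byte-identical tables. Paired-cohort configs derive their
  two seeds from one master seed via `SeedSequence`.

What the generator does **not** emulate: assay missingness and
below-detection-limit censoring, non-Gaussian concentration tails,
diagnosis progression across timepoints within a participant (a
participant's label is constant across visits), informative censoring,
and genuine response-factor differences between species. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data features.

## Numerical choices and problem sizes

* Logistic/Cox separation is flagged at |beta| > 15 or SE > 50, or on
  solver non-convergence; flagged fits carry p = NaN and shrink the FDR
  family.
* Standardisation tolerances: column means < 1e-8, SDs within 1e-8 of 1.
* The Newton solvers use step-halving line searches and report
  non-convergence instead of diverging under separation.
* Test-suite and acceptance-script problem sizes: parameter recovery at
  n = 2000 (logistic) and n = 1500 (Cox); null FDR over 20–50 cohorts of
  n = 500 with a 40-species panel; meta power over 15–50 seed pairs at
  n = 800/cohort; cluster recovery over 20 seeds at n = 500; the
  end-to-end discovery/replication run at n = 800 per cohort with the full
  200-species default panel, 10×10 CV for logistic discovery (3 repeats
  for Cox discovery in the acceptance script) and 200 replication repeats.

## Known limitations

* The dynamic hybrid cut reproduces the algorithm's contract; cluster
  boundaries on borderline branches may differ from other
  implementations.
* Continuous NRI on pooled out-of-fold scores inherits that metric's
  sensitivity to any directional signal; its CI over CV repeats reflects
  fold randomness, not sampling variability.
* Repeated timepoints are reduced to one row per participant (last sample
  for prevalent, baseline for incident); no mixed-effects modelling of the
  longitudinal structure.
* Penalised-regression alternatives to stepwise AIC selection and
  external-population calibration are out of scope.
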