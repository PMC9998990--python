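# Methods

## The model

`mutpanel` implements a mutation-count biomarker for immunotherapy efficacy
in non-small-cell lung cancer (NSCLC). Given a panel of genes
G = {g_1, …, g_m} and a threshold k, a patient whose tumour carries somatic
mutations in at least k panel genes is called **MT** (mutant; predicted to
benefit from immune-checkpoint inhibition) and otherwise **WT**. The bundled
default is an 18-gene panel with k = 2. The package covers the full life
cycle of such a model:

1. **Cohort assembly** (`cohort_io`) — parse MAF-like variant tables and
   clinical follow-up, apply variant-level filters.
2. **Feature construction** (`mutation_features`) — binary samples × genes
   mutation-status matrix, gene-prevalence filter, TMB.
3. **Panel discovery** (`feature_selection`) — random-forest variable
   importance with a sequential backward search (SBS) under stratified
   10-fold cross-validation; the chosen panel is the smallest gene set
   attaining the maximal mean CV accuracy.
4. **Classification** (`panel_classifier`) — the count-threshold call plus
   rule-based comparator biomarkers of the same "≥ m mutated genes of a
   fixed set" shape (KEAP1-driven co-mutation, DDR).
5. **Evaluation** (`survival_eval`) — Kaplan-Meier curves, log-rank tests,
   proportional-hazards regression, ROC/AUC, Wilcoxon rank-sum.
6. **Synthetic cohorts** (`simulate`) — planted-signature generators so the
   whole chain is testable without patient data.

## Variant and cohort filters

Variant-level rules are applied in a fixed order, each removed record
attributed to the first rule that rejects it, so the filter report is
deterministic and conserves counts
(retained + Σ removals = input):

1. copy-number and fusion events (a presence/absence small-variant model is
   undefined for them; this cohort-level exclusion runs first),
2. intronic variants,
3. population allele frequency > 1% (1000 Genomes-style annotation),
4. dbSNP-common flag,
5. synonymous (silent) variants,
6. supporting reads < 50 (strict inequality: a variant with exactly 50
   reads is kept).

Rules that rely on an optional annotation (population AF, dbSNP flag, read
support) pass records lacking the field — public-cohort MAFs often omit
them — and each skip is logged. Every rule is individually switchable in
`FilterConfig` because read-support and population filters are only
meaningful for in-house panel calls, not for pre-cleaned public cohorts.

Gene symbols are uppercased and trimmed; the only alias resolved is
`BRAC2 → BRCA2`, a typo that circulates in published DDR gene lists.
After matrix construction, genes mutated in fewer than 3 samples are
dropped (inclusive boundary: exactly 3 is kept).

## TMB

TMB = (retained nonsynonymous SNVs + indels) / megabases sequenced.
`panel_size_mb` has no default — it is a property of the assay (~1.1 Mb for
large targeted panels, 30–38 Mb for exomes) and silently guessing it would
corrupt the scale. TMB-high is `tmb >= 10` mutations/Mb (inclusive).
Mutation multiplicity is kept for TMB but collapsed to presence/absence for
the model matrix. TMB is computed on all retained variants before the
gene-prevalence filter, since burden is a property of the tumour, not of
the recurrent-gene universe.

## Outcome binarization

The discovery classifier needs a binary outcome. Two schemes are
implemented:

* `event_indicator` — label = the event flag at last follow-up.
* `alive_at_horizon` (default, horizon 12 months) — label 1 iff death
  before the landmark; samples censored before the landmark are excluded
  (logged).

The landmark scheme is the default because under administrative censoring
the raw event indicator conflates follow-up length with outcome: when most
non-protected patients die well before the administrative cutoff, the event
indicator approaches a constant and an accuracy-driven search has almost
nothing to select on. A 12-month landmark is a standard clinically
meaningful horizon for advanced NSCLC and yields a roughly balanced label
under the simulator's default survival scales.

## Panel discovery

* Forest: scikit-learn `RandomForestClassifier`, 100 trees (the library's
  default forest size), balanced class weights, Gini impurity variable
  importance. Permutation importance is available via
  `RfConfig(importance_kind="permutation")`.
* Accuracy: mean over seeded, label-stratified 10-fold cross-validation
  (folds reduce automatically if the minority class is smaller than 10).
* Backward search: at each iteration the current subset is scored, genes
  are re-ranked by importance averaged over the ten fold fits (recomputed
  every iteration, never frozen from the first fit), and the lowest-ranked
  `step` genes are dropped. The step follows the adaptive schedule
  (≥400 features: 100; ≥150: 50; ≥51: 20; below that: 1) until one gene
  remains. Exact importance ties are broken by gene name so traces are
  bit-for-bit reproducible.
* Choice: among iterations within `tie_tolerance` (default 0) of the best
  mean CV accuracy, the fewest-genes iteration wins; remaining ties go to
  the earliest iteration.

## Survival evaluation

* Kaplan-Meier via lifelines; the median is the smallest time with
  S(t) ≤ 0.5, reported as "not reached" when the curve never gets there.
* Log-rank: standard two-group statistic, χ² with 1 df. Two groups with
  zero events return statistic 0 with a warning.
* Proportional hazards: lifelines `CoxPHFitter`, Breslow convention for
  tied event times. On non-convergence (e.g. complete separation) the fit
  is retried with a small ridge penalty (0.1) and flagged `penalized` in
  the output. The MT/WT comparison is reported as the hazard of WT relative
  to MT, so HR > 1 means the MT group survives longer; the orientation
  string is carried in every result row.
* ROC/AUC: Mann-Whitney formulation (ties count ½), so a constant score is
  exactly 0.5 and a binary score reduces to (sensitivity + specificity)/2.
  The AUC reported by the pipeline uses the panel mutant-gene count as the
  score against the same binarized outcome used for discovery, and the
  report records that scheme — AUCs are only comparable under an explicit
  outcome definition.
* Wilcoxon: two-sided Mann-Whitney rank-sum (`scipy.stats.mannwhitneyu`).

## The synthetic cohort generator

`simulate_cohort` draws, per cohort:

* gene-specific prevalences — planted panel genes uniform on [0.01, 0.11]
  (the 1–11% spectrum typical of the recurrently mutated genes such a panel
  is built from), background genes uniform on [0.005, 0.15];
* mutations — independent Bernoulli per (sample, gene);
* survival — exponential (Weibull shape exposed for robustness tests) with
  hazard = baseline · exp(−effect); default baseline 1/12 events/month
  (median ~8.3 months untreated-benefit), effect = log 5 ≈ 1.6 for samples
  with ≥ 2 planted mutations (`threshold_group` mode; the planted truth has
  exactly the model's count-threshold form) or proportional to the planted
  count (`per_gene_additive`, for robustness when the truth deviates from
  the threshold form);
* administrative censoring at 40 months (~3.3 years of follow-up).

Defaults are n = 400 samples × 300 genes with 18 planted — a mid-sized
ICI-treated NSCLC cohort. `make_null_cohort` keeps the mutation process and
sets the effect to zero: the specificity control, mirroring a non-immunotherapy
cohort where the panel should predict nothing.

What the generator does **not** emulate: gene-gene co-occurrence and
mutual exclusivity, per-gene mutation multiplicity, panel-versus-exome
territory differences, non-proportional hazards, covariate structure
(age, histology, line of therapy), or loss to follow-up before the
administrative horizon. Passing tests therefore demonstrate the machinery
and its statistical calibration under the stated generative model, not
clinical performance on real cohorts.

## Problem sizes used by the test suite

Statistical tests run at the scales they document: null calibration of the
log-rank test uses 1000 cohorts of n = 200; hazard-ratio coverage and
specificity use 50 replicates at n = 400; panel recovery runs the full
backward search on ten cohorts at the default n = 400 × G = 300 scale;
byte-determinism uses a reduced cohort (n = 120, G = 30, 20 trees), since
determinism is scale-free. Logic tests use toy matrices and small forests.

## Known limitations

* **Rare planted genes are not individually identifiable at default
  scale.** A gene mutated in 1–4% of 400 samples contributes its survival
  signal through a handful of carriers; its marginal association is well
  inside the noise band spanned by ~280 background genes, and the
  count-threshold effect dilutes each gene's conditional signal further.
  Recovery of the planted panel is therefore partial by construction at
  n = 400, concentrated in the higher-prevalence planted genes; the
  recovery acceptance test documents the achieved level honestly rather
  than relaxing itself.
* The SBS accuracy trace is a noisy function of subset size; with
  `tie_tolerance = 0` the chosen subset can ride CV noise. Repeated CV
  would smooth this at proportional cost.
* The count-threshold model treats all panel genes as exchangeable; no
  per-gene weights are fit anywhere, which is the model's stated virtue
  (trivially portable to any panel assay) and its statistical limitation.
* An APOBEC gene-status comparator is supported as a rule shape but ships
  no gene list; published definitions vary, and the package refuses to
  guess one.
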