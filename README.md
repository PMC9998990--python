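# mutpanel

Mutation-count gene-panel modelling of immunotherapy efficacy in non-small-cell
lung cancer (NSCLC).

Immune-checkpoint inhibitors help only a subset of NSCLC patients, and the
established genomic marker — tumour mutational burden (TMB) — separates
responders imperfectly. An alternative biomarker family counts somatic
mutations within a small fixed gene panel: a patient is called **MT**
(mutant, predicted to benefit) when at least *k* of the panel's genes are
mutated, and **WT** otherwise. With the bundled default — an 18-gene NSCLC
panel and *k* = 2 — the call needs nothing beyond a standard targeted-panel
mutation report, which is what makes the model clinically portable.

`mutpanel` is for computational biologists who want to build, apply or
stress-test such a model:

* **discover** a panel from a training cohort: random-forest variable
  importance with a sequential backward search (SBS) under stratified
  10-fold cross-validation, keeping the smallest gene set with maximal mean
  CV accuracy;
* **classify** samples with the count-threshold rule, alongside rule-based
  comparator biomarkers (KEAP1-driven co-mutation: ≥2 of
  KEAP1/STK11/PBRM1/SMARCA4; DDR: ≥1 of MSH2/MSH6/PMS2/POLE/BRCA2);
* **evaluate** with survival statistics: Kaplan-Meier curves and medians,
  log-rank tests, uni-/multivariate proportional-hazards regression
  (HR reported as WT relative to MT, so HR > 1 favours MT), ROC/AUC,
  Wilcoxon rank-sum;
* **simulate** NSCLC-like cohorts with planted signatures — sparse binary
  mutations at a 1–11% prevalence spectrum and exponential survival whose
  hazard drops by a factor ≈5 for samples carrying ≥2 planted mutations —
  so the whole chain runs and is tested with no external data.

Input formats are MAF-like tab-separated mutation tables plus a clinical
table (sample, time in months, event flag); variant-level filters
(intronic, population frequency >1%, dbSNP-common, synonymous, <50
supporting reads) and the ≥3-samples gene-prevalence filter are applied
during cohort assembly. See `docs/methods.md` for the full model
description and numerical conventions.

## Worked example

Discover a panel on a simulated 300-patient cohort in which 8 of 60 genes
carry a planted survival signal:

```python
import mutpanel as mp
from mutpanel.pipeline import RunConfig, run_discovery
from mutpanel.simulate import SimulationConfig, simulate_cohort

sim = SimulationConfig(n_samples=300, n_genes=60, planted_genes=8, seed=7,
                       planted_prevalence_range=(0.08, 0.20))
cohort, truth = simulate_cohort(sim)
panel, trace, report = run_discovery(RunConfig(out_dir="demo", seed=7),
                                     cohort=cohort)
```

which prints (via the report dictionary):

```
planted:  ['SG01', ..., 'SG08']
chosen :  ['SG02', 'SG03', 'SG06', 'SG08', 'SG09', 'SG17', 'SG30', 'SG39', 'SG44', 'SG59']
best CV accuracy: 0.6667
MT/WT: 150 150
medians mt/wt: 15.7 9.2
HR(WT vs MT): 1.58 [1.23, 2.03]  p 3.98e-04
logrank p: 3.55e-04   auc: 0.642
```

Reading this: the backward search kept a 10-gene panel (4 of the 8 planted
genes plus 6 passengers — rare planted genes are hard to separate from
background at this sample size). Applying the ≥2-mutated-genes rule splits
the cohort 150/150; the MT group's median overall survival is 15.7 months
against 9.2 for WT, the hazard of WT patients is 1.58× that of MT
(95% CI 1.23–2.03), and the mutant-gene count discriminates the 12-month
survival outcome with AUC 0.64.

The same stages are available from a shell:

```bash
mutpanel simulate --out-dir cohort1 --seed 7
mutpanel discover --mutations cohort1/mutations.maf.tsv \
                  --clinical cohort1/clinical.tsv --out-dir run1 --seed 7
mutpanel validate --mutations cohort2/mutations.maf.tsv \
                  --clinical cohort2/clinical.tsv \
                  --panel run1/panel.json --out-dir val1
```

`run1/` holds `panel.json`, `trace.json` (per-iteration feature counts and
CV accuracies), `calls.tsv`, `report.json` and a config snapshot; runs with
identical config and seed are byte-identical.

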