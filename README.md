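# rulemine

Exhaustive supervised rule mining for discretized multi-source biomedical
data, with rule-based L2-logistic classification and a repeated-holdout
evaluation protocol.

## The problem

High-dimensional ¹H-NMR metabolomics tables (and the clinical, chemistry
and pathology variables that accompany them) are usually analysed with
*global* variable selection: each variable is scored as a whole against the
outcome. Local phenomena — a subgroup of patients concentrated in a narrow
range of one variable, or in a joint corner of two — are invisible to such
scores. `rulemine` instead enumerates **every** candidate subgroup
description of dimension 1 or 2 over discretized variables and keeps the
statistically interesting ones as *rules*.

The motivating application is chronic kidney disease staging: classifying
patients with renal failure (eGFR < 60 ml/min/1.73 m², target modality
`below60`) against those without (`at_least_60`) from 0.04-ppm urine NMR
buckets discretized into 10 quantile bins, at a heavily imbalanced cohort
size of about 110 subjects.

## The method

A **rule** is a conjunction of one or two variable conditions — a
contiguous bin range `[a, b]` of an ordinal variable, or a category subset
of a nominal one — together with a target modality:

```
{variable: 'bucket 2.14'; condition: bins 1 to 4}
```

Mining proceeds per modality in two steps:

1. **Exhaustive generation and selection.** All k(k+1)/2 ranges per
   ordinal variable (all non-empty category subsets per nominal variable),
   and for 2D all cross products over variable pairs, are scored with two
   quality measures: the *rule modality size* n₊ (covered subjects carrying
   the modality) and the one-proportion **z-score**

   z = (p_r − p₀) / √(p₀(1 − p₀)/n_r),

   where p_r is the modality proportion inside the rule's support of size
   n_r and p₀ the population proportion. Rules with n₊ ≥ 10 and z ≥ 1.96
   are kept.
2. **Minimization.** Nested rules on the same variables are de-duplicated:
   a rule included in a larger rule with a z at least as high is dropped,
   as is a rule covering a strictly smaller rule with a strictly higher z.

Each surviving rule becomes a binary *local variable* (its support
indicator), the input of an L2-penalized logistic regression. Three model
types are compared: **global** (χ² test per variable with Bonferroni
correction at α = 0.05, logistic regression on the selected raw variables),
**local 1D** (1D rules mined on the χ²-selected variables) and **local
1&2D** (1D and 2D rules). Evaluation uses 100 stratified 80/20 holdout
splits, an inner CV (10 runs of 2 folds) for the inverse penalty C, a
label-permutation test for significance, and mean pairwise Jaccard overlap
of selected feature sets for stability.

## Worked example

`examples/01_mine_rules.py` builds a 110-subject synthetic cohort (24/86
class split) with two planted 1D shifts and one margin-balanced 2D
interaction, then mines rules:

```
cohort: 110 subjects, 22 variables, classes {'below60': 86, 'at_least_60': 24}

24 significant minimized rules (modality size >= 10, z >= 1.96):
  [at_least_60] z= 8.15 covers  21 (20 of the modality)  {variable 1: 'bucket 0.16'; condition: bins 6 to 10 AND variable 2: 'bucket 0.20'; condition: bins 6 to 10}
  ...
  [    below60] z= 4.28 covers  83 (81 of the modality)  {variable: 'bucket 0.16'; condition: bins 1 to 5}

1D rules: 5, 2D rules: 19
```

Each line reads: among the `coverage` subjects satisfying the condition(s),
`modality_size` carry the rule's modality, an enrichment `z` standard
errors above the population rate. The planted pair is recovered only by 2D
rules — its two variables are deliberately generated with flat margins, so
no 1D rule on them can pass the threshold.

The other examples run the preprocessing chain on synthetic spectra
(`02_preprocess_spectra.py`) and the three-model evaluation protocol
(`03_evaluate_models.py`).

## Command line

A thin CLI wraps the library: `rulemine simulate | preprocess | mine | fit
| evaluate | report`. For instance

```bash
rulemine simulate --out cohort.csv --seed 3
rulemine mine --data cohort.csv --out rules.jsonl --dims 12
rulemine evaluate --data cohort.csv --model-type local_1d --outdir report/
```

writes the dataset (CSV + metadata sidecar), the minimized rule set (JSON
lines), and the evaluation tables (summary row, per-run metrics, variable
frequencies, interaction matrices).

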