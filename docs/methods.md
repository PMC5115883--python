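# Methods

This note documents the statistical procedures implemented in `rulemine`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

A `DiscretizedDataset` is a subjects × variables table of level codes with
a binary target. Ordinal variables (NMR buckets, discretized clinical
measurements) carry integer codes 1..k; nominal variables carry category
labels. The target has exactly two modalities, canonically
(`below60`, `at_least_60`) for eGFR < 60 vs ≥ 60 ml/min/1.73 m²; the names
are configurable. Numeric tables are imputed before discretization with the
per-variable sample median (midpoint of the two central order statistics
for even counts); a fully missing variable is an error, and imputation is
idempotent.

## NMR bucket preprocessing

The chain converts a bucketed ¹H-NMR intensity table into ordinal
features:

1. **Binning** — integration over half-open equidistant buckets
   `[left, left + width)`; defaults `width = 0.04 ppm` over
   `[0.16, 9.00) ppm`, giving 221 buckets. Buckets are named by their left
   edge rounded to two decimals (`bucket 3.16`).
2. **Region deletion** — urea (5.45–6.48 ppm) and residual water
   (4.48–4.96 ppm) are removed. The boundary convention is a configuration
   switch, `overlap_rule`: `"overlap"` (default) drops any bucket with
   nonzero intersection and leaves 183 buckets; `"contained"` drops only
   buckets lying entirely inside a region and leaves 184. Legacy bucket
   tables for this kind of cohort are reported with 184 buckets, a count
   that the any-overlap rule cannot produce on this grid; since the exact
   historical convention is unrecoverable, both are provided and the
   discrepancy is documented here rather than silently forced.
3. **Integral normalization** — each spectrum is rescaled to a constant
   total (default 100), the standard dilution correction for urine. An
   all-zero spectrum is an error naming the subject.
4. **Pareto scaling** — per bucket: subtract the mean, divide by the
   square root of the standard deviation. The sd convention is a flag
   (`sd_ddof`, default 1 = sample sd); zero-variance buckets map to zeros.
5. **Quantile discretization** — per bucket, interior bin edges at the
   i/q empirical quantiles (linear interpolation, default q = 10),
   duplicate edges merged, right-closed intervals (a value equal to an
   edge falls in the lower bin). Codes are monotone in the raw values and
   invariant under strictly increasing transformations, so the
   discretization depends only on ranks.

The chain preserves subject count and order throughout.

## Rule mining

Candidate conditions of an ordinal variable with k levels are all
contiguous ranges `[a, b]`, k(k+1)/2 of them; for a nominal variable, all
non-empty category subsets, guarded at 6 categories (beyond that the user
is asked to pre-group). 2D candidates are the cross products over unordered
variable pairs; variables are never paired with themselves, and dimensions
≥ 3 are out of scope (the candidate space grows too fast to enumerate
exhaustively and minimization is not designed for it).

Rule quality uses two measures. The *modality size* is the number of
covered subjects carrying the rule's modality. The *z-score* is the
one-proportion statistic

    z = (p_r − p0) / sqrt(p0 (1 − p0) / n_r)

with p_r the modality proportion inside the rule, p0 the population
proportion and n_r the support size. This is the simplest statistic
consistent with comparing "the proportion in the rule against the
population"; a hypergeometric-variance variant would shrink the
denominator for large supports, but the one-proportion form is kept as the
default because it is the direct reading of that comparison and is
monotone in the same quantities. Selection keeps rules with modality size
≥ 10 and z ≥ 1.96, both inclusive. The thresholds are recorded in the rule
set's provenance.

**Minimization** removes redundant nested rules. Containment is defined
condition-wise on identical variable sets only — a 1D rule is never
compared against a 2D rule, even on a shared variable, because redundancy
is only meaningful among rules describing the same variable space. A rule
R is deleted when a strictly larger rule L exists with z(L) ≥ z(R), or
when a strictly smaller rule S exists with z(S) > z(L). The asymmetric tie
rule (≥ upward, strict > downward) prevents mutual annihilation of nested
equal-z rules: the larger one survives. The filter is applied
simultaneously over the input; its survivor set provably contains no
nested pair, which makes the operation idempotent, and it coincides with a
literal pairwise dominance filter (property-tested against one).

Scoring is vectorized — per variable the condition support masks are
stacked, and 2D candidate boxes are scored with mask matrix products — but
the per-candidate reference path (`select_significant`) is kept and tested
to agree with the fast path.

## Predictive models

* **global**: per variable, a Pearson χ² test of independence on the
  levels × target contingency table (no continuity correction); variables
  with p ≤ 0.05/m (Bonferroni over the m testable variables; constants are
  skipped) are selected. The classifier sees ordinal level codes as single
  numeric columns and one-hot nominal categories, so the model's
  complexity equals the number of selected variables.
* **local_1d** / **local_1and2d**: rules are mined on the χ²-selected
  variables (dimension 1, or 1 and 2), and the classifier sees one binary
  column per rule; complexity is the number of rules. A `mine_variables`
  override ("all", or an explicit list) widens the mining universe — this
  is needed to surface pairwise interactions whose margins carry no 1D
  signal at all, which the χ² preselection is structurally blind to.

Classification is L2-penalized logistic regression (inverse penalty C,
intercept unpenalized, lbfgs, tolerance 1e-8), fitted on the binary rule
features or encoded raw variables. No class weighting is applied; the
class imbalance is handled by reporting F1. If selection leaves no
features, the model degrades to an intercept-only majority predictor with
a logged warning.

## Evaluation protocol

The dataset is split into stratified 80/20 train/test pairs `n_splits`
times (default 100); per class the test set takes round(class share × 20%)
subjects, so a 24/86 cohort of 110 yields 22-subject test sets split 5/17.
Per split, C is chosen from {0.001, 0.01, 0.1, 1, 10, 100} by an inner CV
of 10 runs of 2 stratified folds — 2 folds keep enough minority subjects
per fold — with the entire selection/mining pipeline re-run inside each
fold (no information from the validation fold reaches rule selection; this
is asserted by an instrumentation test). Ties break toward the smallest C.
The most frequent choice C* is then fixed and every split's model rebuilt
with it; test F1 (macro-averaged by default — a constant-majority
predictor scores ≈ 0.44 macro on the 5/17 test split, so values near 0.7
are meaningfully above chance; per-modality averaging is available),
complexity and the selected feature identities are recorded.

**Stability** is the mean (± sd) pairwise Jaccard similarity of
selected-feature sets over all split pairs. Global models compare variable
names; local models compare exact rule identities (variables, conditions,
modality). Two empty sets count as identical.

**Significance** uses a label-permutation test:
p = (1 + #{permuted ≥ observed}) / (B + 1) with B permutations (default
1000). The test statistic — for the observed value and every permutation
alike, so the two are exchangeable — is the mean test F1 over
`n_perm_splits` fresh stratified splits at fixed C*. Recomputing all 100
splits per permutation would cost ~100 000 pipeline fits, so
`n_perm_splits` defaults to 5 with a full-fidelity override.

All randomness flows from one master seed that fans out independent child
streams (outer splits, inner CV, permutations); a fixed seed makes the
whole report bit-reproducible.

## Synthetic data

The generator draws study-condition cohorts: 110 subjects, 184 ordinal
bucket variables with 10 bins, class sizes 86/24, one age-like ordinal
clinical variable (upper bins enriched in the renal-failure class) and one
unassociated binary nominal. Unplanted buckets are uniform over bins
independent of class.

* **Planted 1D shifts**: the variable is drawn from an enriched bin range
  with a set probability for the `below60` class and from the mirrored
  range for `at_least_60` (low relative concentration in one class, high
  in the other). The default enrichment used by the recovery analyses is
  0.9, which puts the planted range's realized z above 1.96 in essentially
  every draw at n = 110.
* **Planted 2D interactions**: a variable pair is drawn, with a set
  probability, from the low-low/high-high diagonal corners for `below60`
  and from the anti-diagonal corners for `at_least_60` (symmetric corner
  placement). Both corner choices are equiprobable, so each variable's
  margin stays exactly uniform in both classes: 1D mining and the χ² test
  are structurally blind to the pair, and only 2D mining can recover it.
  This is precisely the property that makes the added value of the 1&2D
  model testable.

The spectra generator emulates only what the preprocessing chain needs:
sums of Lorentzian peaks with class-dependent amplitudes on a dense
unresolved background. The background carries per-subject, per-bucket
biological variability (relative sd 0.2); without it, the
integral-normalization closure of a single class-dependent peak would leak
a detectable anti-correlated signal into every bucket, which is not how a
many-metabolite urine matrix behaves. No chemical-shift physics, peak
overlap structure or inter-metabolite correlation is modelled, so passing
tests demonstrate the pipeline's statistical behaviour, not spectroscopic
realism.

## Problem sizes and numerical choices

The library defaults encode the full protocol (100 splits, 1000
permutations). The test suite and `scripts/acceptance.py` run scaled-down
versions — typically 5–25 splits, 49–99 permutations, 20–40 buckets —
chosen as the smallest sizes at which the checked properties are stable;
the statistics themselves are unchanged by the scaling. The logistic
solver runs at tolerance 1e-8 (fixed for reproducibility); quantile edges
use linear interpolation; all enumeration orders are deterministic
(declared variable order, ranges lexicographic by (a, b)).

## Known limitations

* Rules of dimension ≥ 3, L1/elastic-net classifiers, calibration and
  multiclass targets are out of scope.
* Full-width 2D mining over all 184 buckets (≈ 5 × 10⁷ candidate boxes)
  is allowed but guarded by a budget warning; the intended use is mining
  within a preselected variable set.
* The minimization order is a partial dominance order among nested rules
  only; overlapping non-nested rules are all kept, which can leave
  substantial redundancy in dense rule sets (visible as large local-model
  complexities).
* The permutation p-value's default reduced statistic (5 splits) is
  noisier than a full-fidelity recomputation; its floor is
  1/(B + 1).
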