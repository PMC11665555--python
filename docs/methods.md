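# Methods

This note documents the statistical procedures, the synthetic-data
design, the numerical choices, and what the test suite does and does not
establish.

## Master regulator analysis

Given regulons (TF → target sets), a DEG table and the assayed genome,
each regulon is reduced to its in-universe targets (exact, case-sensitive
identifier matching after whitespace trimming; unmapped identifiers are
dropped and counted, never fuzzy-matched) and tested for
over-representation among DEGs:

* **Fisher exact test**, one-sided by default: the upper hypergeometric
  tail P(X ≥ a) at the observed overlap *a* given margins
  (universe, regulon, DEG set). One-sided because the question is which
  TFs *drive* the differential program; depletion is not a selection
  criterion. A two-sided switch exists (`fisher_alternative`).
* **Permutation null**: B gene sets of the DEG-set size drawn uniformly
  without replacement from the whole assayed genome; the empirical p is
  the add-one estimator (1 + c)/(B + 1), which cannot report 0 from
  finite resampling and is bounded below by 1/(B + 1). B defaults to
  10,000. Inside `run_mra` one batch of B draws is shared across all
  TFs — the draws are genome resamplings of the DEG set, so the same
  batch is the correct comparator for every regulon, and it makes
  B = 10,000 × hundreds of TFs tractable. The permutation preserves only
  the DEG-set size: no fold-change sign, no regulon interaction mode.

Selection requires both p-values below their α (0.05 each by default).
BH-adjusted columns are reported for convenience but never alter the
selection rule. The universe is *all genes in the DEG table* — the
tested genome — not the union of regulons. Output ordering is
deterministic: Fisher p, then permutation p, then TF name.

## Joint pathway analysis

Pathway graphs have typed nodes (gene | metabolite) and undirected
edges. Each omics layer is tested separately against its own assayed
universe (all genes in the DEG table; all metabolites on the panel),
because the two platforms measure different feature spaces. Per-layer
enrichment is the one-sided hypergeometric tail, the same
over-representation logic as the MRA Fisher test.

Equal consideration of the two layers is realized as **Fisher's method**:
X = −2(ln p_gene + ln p_met) referred to χ² with 4 df. This is the
simplest p-combination that weighs both layers equally; a Stouffer
variant is available behind `combine_method="stouffer"` and is
deliberately non-default. Zero p-values are clamped to the smallest
positive float (the log diverges), and the combined p is floored there
too so the (0, 1] contract survives survival-function underflow.

**Impact** is the degree-centrality share of the hit nodes:
Σ degree(hits) / Σ degree(all nodes). Raw degree sums are used rather
than (n−1)-normalized centralities — the ratio is identical under any
constant normalization and raw sums avoid division by zero on singleton
graphs. An edgeless graph has impact 0. Ranking is combined p
ascending, impact descending as tie-break, then pathway id.

This module implements the *described* behaviour of joint pathway
enrichment with degree-centrality topology weighting; it is not a
bit-exact clone of any web service's internal scaling.

## Metabolite screen

One-way fixed-effects ANOVA per metabolite across sample groups, on
log2-transformed abundances by default (abundances are positive and
right-skewed; the raw scale is available by flag, and the worked
three-group example in the tests uses it). Metabolites with zero
within-group variance are flagged degenerate, get no p-value and are
excluded from the BH family. Metabolites with any missing value are
dropped with a logged count — imputation is out of scope.

The post hoc test is **Tukey HSD** (all pairwise comparisons,
studentized-range family-wise adjustment) — the standard all-pairs
companion to one-way ANOVA; pairwise t with BH is available as a switch.
Differential enrichment is *called* at raw ANOVA P < 0.05 (the screen's
significance level, and what feeds the joint pathway query); BH-adjusted
values are reported alongside for the reader.

Reference normalization maps each value to log2(value / geometric mean
of the reference group for that metabolite), so reference rows average
to zero exactly. The heatmap export selects the k smallest-p metabolites
(ties broken by name), clusters rows by Euclidean distance with average
linkage, and writes the leaf order as data (TSV), not an image.

## Survival screen

Kaplan-Meier, log-rank and Cox are implemented in-package because the
cutpoint scan performs thousands of single-covariate fits and the
estimators themselves are part of the screen's contract; statsmodels
(`PHReg`, Efron ties) and lifelines serve as independent oracles in the
test suite, where agreement to ~1e-9 is asserted.

* **KM**: product-limit estimator; right-continuous, non-increasing,
  starts at 1; a fully censored sample is a flat curve at 1.
* **Log-rank**: two-group statistic with the hypergeometric variance at
  each distinct event time (ties handled there), χ²₁ reference.
* **Cox**: Newton-Raphson on the Efron-corrected partial likelihood,
  fitted on an internally standardized covariate for conditioning and
  mapped back; Wald 95% CI from the observed information. Efron was
  chosen over Breslow for its behaviour under heavy ties at negligible
  cost; one consequence (covered by a test) is that duplicating every
  subject shifts the estimate slightly — duplication *creates* ties —
  whereas under Breslow it would be exactly invariant. Monotone
  likelihoods (complete separation) are flagged non-converged with a
  diagnostic instead of a silently divergent estimate. Times are
  right-censored only; no interval censoring, no multivariable
  adjustment, no competing risks.

**Median split**: high group = expression ≥ median, ties going high (one
side must be chosen; this one is documented and tested).

**Cutpoint scan**: candidate cutoffs are quantile-spaced observed values
inside the configured window (default 41 points across the 10-90%
quantiles, snapped upward to observed values so the q = 0.5 candidate
reproduces the median split *exactly* for any cohort size). The default
is a percentile-scale grid rather than every distinct observed value
(available via `n_cutoffs=None`) for three reasons: the min-p argmin
wanders only a few subjects around a true hazard threshold, so
percentile resolution is the meaningful scale of recovery; the HR trace
is far more stable; and the scan stays fast at any cohort size. The
chosen cutoff follows `min_p` by default (ties: larger |log HR|, then
lower cutoff); `max_abs_loghr` is the alternative. The chosen-cutoff p
is a minimum over many correlated tests and is reported with an explicit
selection-bias note; no multiplicity correction is applied because none
is part of the screening procedure, and the test suite demonstrates the
inflation empirically (min-p rejection under the null far exceeds 5%).

## Synthetic-data generator

The generator is first-class, tested code. All generators are pure
functions of the simulation spec: one master seed, with per-stage
substreams keyed by stage name so stage reordering never perturbs
another stage's draws. Planted quantities are emitted in a sidecar truth
record so tests assert recovery without re-deriving them.

Defaults encode the study-scale conditions the pipeline targets: a
5,000-gene universe with 50 regulons of 50-200 targets and a 400-gene
DEG set; 3 planted TFs at odds ratio 8; 12 pathways mixing gene and
metabolite nodes (random spanning tree plus extra edges, hence connected
by construction); a 147-metabolite panel across three 3-sample groups
(parental / resistant / resistant-knockout); and a 300-subject cohort
with HR 2.35 per SD of expression and 20% censoring.

* **DEG planting** is weighted sampling without replacement
  (Efraimidis-Spirakis keys log(u)/w) with weight = odds ratio on
  planted-TF targets and 1 elsewhere — exactly uniform at odds ratio 1
  (verified against the hypergeometric mean), saturating as the ratio
  grows. Significant rows carry padj below and |log2FC| above the
  configured cutoffs; effect-size magnitudes are otherwise arbitrary
  and documented as such.
* **Metabolite planting**: ln-abundances are N(μ_m, 1) (log-normal
  values, hence strictly positive with realistic skew); perturbed
  metabolites — the planted pathway's metabolite members — have the
  *second* group's mean shifted by the effect size in standardized
  units, with later groups restored to baseline, emulating a
  resistant-line perturbation that a knockout reverts. With 2-SD shifts
  and n = 3 per group, per-metabolite power is moderate (~0.5 at
  α = 0.05) — deliberately a hard but winnable detection problem.
* **Pathway planting**: the planted pathway draws ~60% of its gene
  members from the DEG set, so both omics layers carry signal for it;
  other pathways sample uniformly.
* **Survival**: exponential event times with log-hazard equal to
  `true_log_hr` × standardized expression (continuous model) or a
  two-level hazard split at a threshold (threshold model). Censoring is
  administrative-uniform on (0, τ) with τ solved numerically (Brent) so
  the expected censoring fraction matches the requested rate.

What the generator does *not* emulate: read counts or the DEG-calling
step (tables are simulated at summary level), LC-MS peak structure,
batch effects, correlated metabolites, non-proportional hazards, or
informative censoring. Passing tests therefore establish the *methods*
behave correctly under their own assumptions — calibrated nulls, planted
signal recovered — not that real cohorts satisfy those assumptions.

## Problem sizes and numerical choices

Monte-Carlo checks use these sizes, chosen to make each property sharp
at desk scale: oracle agreement on 200 random small tables (tolerance
1e-10); permutation exactness on ≤ 12-gene universes at B = 20,000
(3 binomial SEs); MRA null calibration on 1,000 TF-trials at B = 2,000 —
these calibration bundles use a dense overlap geometry (6,000 genes,
2,400 DEGs, regulons of 1,500-3,000) because the permutation p of a
sparse overlap is discrete and conservative, and the calibration
question is about the estimator, not the sparsity; planted-TF recovery
over 100 seeds at the default study scale; survival calibration over
200 seeds (n = 200) and recovery over 100 seeds (n = 1,000-2,000).
Newton iterations stop at |Δβ| < 1e-9 (≤ 50 iterations, |β| > 40 on the
standardized scale treated as separation). Sorting everywhere uses
stable mergesort with named tie-breaks, so all outputs are byte-stable
under a fixed seed.

## Known limitations

The regulon resource is consumed as-is: no confidence-class filtering,
no mode-of-regulation signs, no regulon inference from expression. The
joint pathway module takes user-supplied graphs; it bundles no pathway
database. The survival screens are univariate by design. The min-p
optimal cutoff remains selection-biased; the package flags it rather
than inventing a correction.
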