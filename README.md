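# resistomics

Multi-omics screens for dissecting chemoresistance mechanisms: a tested,
reusable implementation of the computational chain that takes paired
transcriptomic and metabolomic profiles of drug-sensitive versus
drug-resistant cells and produces (1) candidate master-regulator
transcription factors, (2) jointly perturbed pathways, (3) differentially
enriched metabolites, and (4) expression-versus-survival prognostic calls.
It is aimed at computational biologists who have DEG tables, curated
regulons (e.g. DoRothEA-style TF→target sets), a targeted metabolite
panel and survival cohorts, and want the whole chain scripted,
deterministic and testable instead of spread across web tools.

## What it computes

**Master regulator analysis (MRA).** For each TF regulon *R* and the DEG
set *D* inside the assayed genome *U*, the overlap |R ∩ D| is tested
twice: a one-sided Fisher exact test, P(X ≥ |R ∩ D|) for hypergeometric
X with margins (|U|, |R|, |D|); and an empirical null built by drawing
B = 10,000 gene sets of size |D| uniformly from *U* and counting
overlaps, with p = (1 + #{overlap ≥ observed}) / (B + 1). TFs with both
p < 0.05 are selected. A Venn partition utility breaks the DEG-hit
targets of two selected TFs into unique/shared counts.

**Joint pathway analysis.** Significant genes and metabolites are mapped
onto pathway graphs with typed nodes. Each omics layer gets an
upper-tail hypergeometric enrichment p against its own assayed universe;
the layers are combined with equal weight by Fisher's method,
X = −2(ln p₁ + ln p₂) against χ²₄. Topology contributes a
degree-centrality impact, Σ deg(hits) / Σ deg(all) ∈ [0, 1]. Pathways
rank by combined p, impact breaking ties.

**Metabolite screen.** Per-metabolite one-way ANOVA across sample groups
on log2 abundances, BH adjustment across the panel, Tukey HSD post hoc,
log2 fold-change normalization against a reference group, and an
average-linkage hierarchical clustering order for the top-k heatmap.

**Survival screen.** Kaplan-Meier product-limit curves, the two-group
log-rank test, and univariate Cox regression (Newton-Raphson on the
Efron-corrected partial likelihood, Wald 95% CI) — used for a
median-split analysis and an optimal-cutoff scan that traces HR and CI
across dichotomization thresholds in the 10-90% quantile window and
flags the selection bias of the resulting min-p cutoff.

A synthetic-data module generates all five inputs with planted signal
(known master TFs, a perturbed pathway, metabolite shifts, an
expression-dependent hazard), so every stage is exercised and validated
without any external download.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/03_master_regulators.py
```

prints, for the seed-0 bundle (50 regulons over 5,000 genes, 400 DEGs,
TF01-TF03 planted at odds ratio 8, B = 10,000 permutations):

```
4 of 50 TFs selected by the dual criterion (Fisher P < 0.05 and permutation P < 0.05)
selected: TF01, TF02, TF03, TF18
planted:  TF01, TF02, TF03
of 122 DEGs hit by TF01 or TF02: 61 unique to TF01, 5 shared, 56 unique to TF02
```

All three planted master regulators are recovered (TF18 is a
false positive at the 0.05 level); the Venn partition splits the
DEG-overlapping targets of the top two TFs into unique and shared
counts. Continuing with `analysis/04_joint_pathway.py` and
`analysis/05_survival_screen.py`:

```
top pathway: PW01 (gene hits 11, metabolite hits 1, combined p = 1.4e-19, impact = 0.529)
planted pathway: PW01 -> recovered
median split at 0.075: HR = 2.76 [2.13, 3.59], log-rank P = 2.9e-15 (simulated HR 2.35 per SD)
optimal cutoff (min_p) at 0.717: HR = 3.48 [2.60, 4.67], log-rank P = 7.967e-19
```

The planted pathway tops the joint ranking, and the survival screen
recovers a strong hazard-ratio signal — note the optimal-cutoff HR
(3.48) exceeds the median-split HR (2.76), the selection bias the scan
output explicitly flags.

The same stages are available as a CLI (`resistomics simulate|metabo-de|
mra|jointpath|survscreen|run-all`) with `--seed`, `--config` (YAML) and
`--out-dir`; `run-all` writes per-stage TSVs plus a manifest with input
and output checksums, and is byte-reproducible for a fixed seed.

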