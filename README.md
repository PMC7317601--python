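# mirhub

Hub-gene discovery from weighted gene co-expression networks, as a tested,
reusable pipeline.

Studies that nominate candidate disease genes — for example, targets of a
microRNA that are dysregulated in a tumor — typically chain together several
screens: differential-expression and target-prediction overlap, weighted gene
co-expression network analysis (WGCNA) to find a trait-associated module and
its key genes, a standardized-mean-difference meta-analysis of the marker
across independent cohorts, degree filtering of a protein–protein interaction
network, and diagnostic (ROC/AUC) and prognostic (Kaplan–Meier, log-rank)
validation of the final hub genes. `mirhub` implements that whole chain as a
library with a CLI, and pairs it with a synthetic-data module that generates
every input with *planted ground truth*, so each stage — and the end-to-end
flow — is testable without downloading any cohort data.

It is aimed at computational biologists who want the statistics of such a
screen to be explicit, seeded and verifiable rather than buried in a chain of
web tools.

## The statistics at the core

**Co-expression network.** From a genes × samples matrix, the similarity is
the absolute Pearson correlation, S<sub>XY</sub> = |cor(X, Y)|, raised
elementwise to a soft threshold β chosen so the weighted degree distribution
approximates a power law (scale-free topology fit, signed R² ≥ 0.8):
a<sub>XY</sub> = S<sub>XY</sub><sup>β</sup>. Pairs are compared by topological
overlap,

> ω<sub>XY</sub> = (l<sub>XY</sub> + a<sub>XY</sub>) / (min(k<sub>X</sub>, k<sub>Y</sub>) + 1 − a<sub>XY</sub>),  l<sub>XY</sub> = Σ<sub>u</sub> a<sub>Xu</sub> a<sub>uY</sub>,  k<sub>X</sub> = Σ<sub>u</sub> a<sub>Xu</sub>,

and modules are branches of the average-linkage tree on dissTOM = 1 − ω,
subject to a minimum module size, with similar modules merged by eigengene
correlation (merge height 0.25). Each module is summarized by its eigengene
(first principal component); key genes satisfy module membership
|MM| = |cor(gene, ME)| > 0.8 and gene significance |GS| = |cor(gene, trait)| > 0.2
within the module most correlated with the trait.

**Meta-analysis.** Per-study effects are Hedges' g with the usual variance;
pooling is inverse-variance, fixed-effect or DerSimonian–Laird random-effects,
with Cochran's Q, I² = max(0, (Q − df)/Q), the rule "random effects iff
p<sub>Q</sub> < 0.05 or I² > 50%", and Egger's funnel-asymmetry regression
(asymmetric at p < 0.1).

**Network and validation.** Interaction edges with confidence < 0.4 are
deleted, the graph is restricted to its main connected component, and genes
with degree ≥ 8 are intersected with the WGCNA key genes to give hub genes.
Hubs are evaluated by ROC/AUC (trapezoid = tie-corrected rank statistic),
median-dichotomized Kaplan–Meier curves with a log-rank test
(χ² = (O₁−E₁)²/E₁ + (O₂−E₂)²/E₂, HR from the O/E ratio), and hypergeometric
over-representation of module genes against user-supplied gene sets (GMT)
with Benjamini–Hochberg adjustment.

## Worked example

```bash
mirhub demo --outdir demo_run --seed 0
```

generates a 500-gene × 150-sample expression matrix with four planted
co-expression modules (sizes 60/50/40/30, within-module correlation 0.64, the
first module driving a continuous trait at r = 0.5), plus matching
differential-expression, target-prediction, multi-study, interaction-network,
survival and gene-set inputs, and runs every stage. It prints:

```
overlap genes  261
modules        4
key genes      22
hub genes      8
pooled SMD     0.305
I2 (%)         19.8
hub genes: G0058, G0008, G0014, G0001, G0013, G0033, G0037, G0038
```

All 22 key genes and all 8 hub genes come from the planted trait-linked
module (genes G0000–G0059): the screen found the planted signal and nothing
else. The pooled SMD of 0.305 recovers the simulated true effect of 0.3
across the 8 synthetic studies, and I² = 19.8% correctly keeps the
fixed-effect model for this homogeneous draw. `demo_run/run_report.json`
holds the full machine-readable report — module–trait correlations, per-hub
AUCs (0.63–0.69 against the dichotomized trait), the log-rank hazard ratio
(2.07 for a simulated true hazard ratio of 2) and the over-representation
table, where the planted gene set ranks first (p ≈ 1.3e−60).

The same stages are available programmatically (`mirhub.wgcna.run_wgcna`,
`mirhub.meta.meta_analyze`, `mirhub.ppi`, `mirhub.diagnostics`) and as
standalone subcommands (`simulate`, `overlap`, `wgcna`, `meta`, `ppi`,
`diagnose`, `run-all`) that communicate through plain TSV/GMT/JSON files, so
any stage can be re-run on real data that follows the documented formats.

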