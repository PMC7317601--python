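# Methods

This note records the models, the defaults and the numerical choices behind
`mirhub`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic data model

The generators produce every input the pipeline consumes, each with planted
ground truth.

**Expression with planted modules.** Each module m has one latent factor
f_m ~ N(0, 1) over samples; a member gene is
`noise_sd * (sqrt(r) * f_m + sqrt(1 - r) * eps)` with eps ~ N(0, 1) i.i.d.,
so two genes of the same module have correlation exactly r in expectation —
a single-factor model chosen over an explicit covariance factorization
because it is O(genes × samples) and its expected correlation is exact.
Unassigned genes are pure noise and carry label 0, mirroring the "grey"
convention of co-expression analysis. The trait is
`t * f_trait + sqrt(1 - t^2) * eps`, giving cor(trait, factor) = t in
expectation. Defaults: 500 genes × 100 samples (150 in the demo), module
sizes 60/50/40/30, within-module correlation r = 0.64, trait correlation
t = 0.5, seed-deterministic throughout. The within-module correlation is
chosen for testability — strong enough that module recovery is expected, not
guaranteed trivially; real co-expression data rarely advertises its
correlation scale. The trait correlation 0.5 puts the expected gene
significance near 0.4, comfortably above the 0.2 screening threshold while
leaving room for sampling noise to matter.

**Multi-study effects.** Study i draws its own effect
delta_i ~ N(true_smd, tau^2), then cases ~ N(delta_i, 1) and controls
~ N(0, 1). The default benchmark uses the eight observed cohort sizes
(78/88, 9/10, 9/7, 3/3, 8/10, 4/8, 3/3, 372/50 cases/controls), a true SMD
of 0.3, and tau = 0.4 for the heterogeneous regime (which drives I² above
50% in most replicates) or tau = 0 for parameter recovery.

**Interaction network.** Erdős–Rényi with edge probability
mean_degree / (n − 1) and uniform scores; the demo scores span [0.2, 1.0] so
the 0.4 confidence filter removes something.

**Survival.** Exponential event times with baseline rate fixed at 1.0 and
rate `hazard_ratio` in the high group; censoring times are uniform on [0, c]
with c solved numerically (Brent) so the expected censored fraction equals
the requested rate.

**Gene sets.** Uniform random subsets of the background, plus one set equal
to the planted trait-module gene list.

What this emulates — and does not: block-correlated log-scale expression
with a trait-linked module, heterogeneous two-group cohorts, a scored
undirected interactome, group-dependent survival. It deliberately omits
microarray platform effects, normalization artifacts, batch structure,
count-distribution (negative binomial) noise, correlated gene sets and
scale-free interactomes. Passing the benchmarks therefore shows the
*statistics are implemented correctly and recover planted structure under
the stated model*; it does not certify performance on real cohort data.

## Co-expression network construction

Similarity is the absolute Pearson correlation (an unsigned network — the
similarity definition takes |cor|, so no signed variant is offered);
adjacency is the elementwise power S^beta. Diagonal conventions: a_XX = 0
inside the connectivity and shared-neighbor sums, TOM diagonal reported as 1,
dissTOM diagonal 0 — the standard choice that makes dissTOM a valid
dissimilarity. Correlation p-values use the t transform
t = r sqrt((n − 2)/(1 − r²)); with hundreds of samples the approximation is
adequate and no permutation p is computed. An optional pre-step flags outlier
samples whose mean inter-sample correlation z-score falls below −2.5 (off by
default).

**Soft-threshold selection.** For each candidate beta in 1..20 the weighted
connectivity k is binned into ~10 equal-width bins; log10 of the bin
frequency is regressed on log10 of the bin's mean connectivity, and the fit
is scored R² × sign(−slope). Binning k itself (not log k) is deliberate:
equal-width binning on log k flattens heavy lower tails and the index stops
discriminating. Selection returns the smallest candidate with signed
R² ≥ 0.8, considering only candidates whose mean connectivity stays ≥ 1 —
past that point the network is essentially empty, the topological overlap of
every pair saturates toward 0 and the fit index is numerically meaningless.
If no candidate passes, the best-fitting feasible candidate is used. On the
planted benchmark this lands at beta 3–6; on data with genuine scale-free
structure the R² rule dominates.

**Module detection.** Average-linkage hierarchical clustering on dissTOM,
cut at a static height; branches below the minimum module size (default 10)
stay unassigned. The default cut height is data-driven: the midpoint of the
largest gap in the sorted merge heights, considering only positions with at
least `min_module_size − 1` merges below them (earlier gaps cannot yield a
module). The rationale: the dissTOM scale compresses toward 1 as beta grows,
so no fixed height works across the selected beta range, while the gap
between the dense low-height regime (modules assembling) and the
near-ceiling regime (unrelated genes joining) is stable. An explicit float
cut height remains available for data without such a gap. A hybrid step can
reattach unassigned genes to the module whose eigengene they correlate with
above a floor (default 0.3); it is off by default because in the planted
simulations grey genes are noise by construction. This simplified
static-cut-plus-reattachment procedure is not a port of the published
dynamic tree-cut reference; its acceptance check is planted-module recovery,
not label-for-label agreement with that implementation.

**Eigengenes, merging, screening.** The module eigengene is the first right
singular vector of the standardized module expression, rescaled to unit
variance (ddof = 1) and signed to correlate positively with the module's
mean standardized profile. Modules are merged when their eigengene
dissimilarity 1 − cor falls below the merge height (default 0.25), iterating
eigengene recomputation to a fixed point. Key-gene screening takes
|MM| > 0.8 and |GS| > 0.2, both strict, restricted to the module with the
largest |module–trait correlation|; absolute values are used so positively
and negatively trait-tracking genes are screened together.

## Meta-analysis

Hedges' g with J = 1 − 3/(4(n₁+n₂−2) − 1) and
var = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Fixed-effect pooling is
inverse-variance (the appropriate continuous-outcome form; Mantel–Haenszel
weighting applies to binary outcomes). Random effects use DerSimonian–Laird
tau². Confidence intervals use the normal 1.96 multiplier, matching the
convention of the standard meta-analysis tools; no t-based interval.
Summary-level input (n, mean, sd per group) is accepted and reduces to the
same effect computation. Egger's test regresses g/se on 1/se by ordinary
least squares and tests the intercept (two-sided t, k − 2 df; asymmetry at
p < 0.1). Two caveats verified during development: with identical study
sizes the only variation in se comes from the g-dependent variance term, a
mechanical effect–precision coupling that inflates Egger's type-I error —
the null benchmark therefore varies study sizes; and at the observed cohort
sizes the pooled SE is ≈ 0.097, so the ±0.15 recovery band is only ≈ 1.55
SE and the per-replicate recovery probability is ≈ 88% for any unbiased
estimator — recovery is measured on the fixed-effect estimate, the
estimator of record under the homogeneity (tau = 0) the benchmark
stipulates.

## Network filtering and hub nomination

Edges are deduplicated keeping the maximum score over (A,B)/(B,A)
duplicates, self-loops dropped. The score filter keeps edges ≥ 0.4 — the
threshold is inclusive because scores *below* 0.4 are deleted. Degrees are
computed after the score filter and the main-component restriction, in that
order; component-size ties break toward the lexicographically smallest
member so the choice is deterministic. High connectivity is degree ≥ 8
(inclusive); hubs are the intersection with the WGCNA key genes, ordered by
descending degree then name.

## Diagnostics

ROC curves keep every distinct threshold; the AUC is the trapezoid area,
identical to the tie-corrected rank statistic, with the asymptotic normal
Mann–Whitney p for AUC = 0.5. The median split assigns values equal to the
median to the "low" group. Kaplan–Meier estimation delegates to lifelines;
the median survival is the smallest time with S(t) ≤ 0.5 (infinite if never
reached). The log-rank test uses the O/E form
χ² = (O₁−E₁)²/E₁ + (O₂−E₂)²/E₂ with HR = (O₁/E₁)/(O₀/E₀) and
CI = exp(ln HR ± 1.96 √(1/E₁ + 1/E₀)) — the two-curve comparison supports
exactly this; no Cox model is fitted. Over-representation is the
hypergeometric upper tail against a declared background, with
Benjamini–Hochberg adjustment across sets and output ranked by descending
overlap count then ascending p; a conservative EASE-style variant (overlap
reduced by one) is available behind a flag, off by default.

## Pipeline

Stages run overlap → WGCNA (expression restricted to the overlap genes) →
meta-analysis → network filter → hub intersection → diagnostics,
communicating only through files in the run directory so any stage can be
re-run standalone. Configuration errors (a disabled dependency, a missing
input) are raised before anything is written. The run report is JSON with
sorted keys, no timestamps, and a content hash per output, so identical
seeds give byte-identical reports. Threshold defaults: p < 0.05 and
|logFC| > 1 for DEGs (a q < 0.01 preset exists, as both conventions appear
in practice), ≥ 3 prediction databases (5 is the stricter documented
alternative), scale-free R² cut 0.8 with automatic beta, minimum module
size 10, merge height 0.25, |MM| > 0.8, |GS| > 0.2, interaction score ≥ 0.4,
degree ≥ 8, α = 0.05, Egger α = 0.1.

## Problem sizes

The recovery benchmarks use 20 simulations of 500 genes × 100 samples; meta
recovery uses 100 replicates of 8 studies; log-rank calibration uses 2000
null replicates at n = 200; the demo is one 500 × 150 run. These sizes give
stable Monte-Carlo estimates of the benchmark quantities while keeping the
full suite and the acceptance script fast on a single CPU.

## Known limitations

No block-wise decomposition for very large gene sets (the full similarity
and TOM matrices are dense); no signed network or alternative TOM variants;
no trim-and-fill, subgroup or meta-regression analysis; no time-dependent
ROC or Cox modeling; no GSEA-style ranked enrichment. Differential
expression statistics are consumed, not computed — the pipeline starts from
a statistics table. The static-cut module detector assumes a height gap
between module and background merges; data with a continuum of co-expression
strength may need an explicit cut height.
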