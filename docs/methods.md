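# Methods

## Scope and model

The package reconstructs a cross-study meta-analysis design: several
independent two-group (control vs. chronic inhaled endotoxin) murine lung
expression studies, each on its own microarray platform, are analyzed
separately and then integrated at the gene level (intersection signature
over a common background, with exact overlap statistics) and at the pathway
level (per-study hypergeometric enrichment merged into an enrichment map).
The integrated signature is validated on an independent four-condition
exposure study (air / LPS / smoke / LPS+smoke) by subsampled consensus
clustering against a random-signature null.

Because the original raw arrays were never deposited publicly, a synthetic
data module is a first-class part of the package: every downstream statistic
is exercised against planted ground truth rather than against irrecoverable
data.

## Synthetic data generator

`generate_multistudy` draws a master universe of `genes_master` genes
(default 2000, each with an MGI-style symbol and, for 95%, an Entrez ID;
5% carry `NA` Entrez to exercise the symbol fallback). Each study's platform
is a random subset of `round(universe_frac × genes_master)` genes (default
70%), **forced to contain every signature gene** — real platforms overlap
only partially, and forcing guarantees that the planted intersection is
recoverable by construction, which is the property the downstream tests
need. Per-study group sizes default to (8, 6, 4) mice per group, matching
the designs of the three studies the analysis emulates; genes carry 1–3
probes (uniform), probe-level baselines are `baseline_mean` (8.0 log₂) plus
gene- and probe-level offsets, and within-group noise is Gaussian with
`noise_sd` (default 0.5 log₂ units).

Differential expression is planted as a mean shift of
`effect_size × noise_sd` (default 3.0 × 0.5 = 1.5 log₂ units) in the exposed
group, on the shared signature genes (default 100) and on
`private_de_per_study` study-specific genes (default 150). Signature
directions are 50% up / 50% down, fixed by the seed and shared across
studies. Private DE sets are drawn disjoint from the signature **and from
each other** so that the planted intersection is exactly the signature; this
makes recovery measurable without deconvolving chance private overlaps. The
paper-scale designs report no per-study effect sizes or variance structure,
so these defaults are stand-ins chosen at the scale typical of strong
microarray responses; all are exposed in `SimulationConfig`.

`generate_multicondition` builds the four-condition study (6/5/6/5 samples).
Each condition label maps to a scalar shift magnitude applied to the
signature genes. With the default `sign_mode="random"` each (gene,
condition) pair receives an independent ± sign, so two conditions sharing a
magnitude (LPS at +2 and LPS+smoke at +2, with smoke at +4) still have
distinct per-gene fold-change patterns and hence distinct expression
centroids — this mirrors multi-exposure data, where each exposure has its
own signature profile rather than a uniform scalar shift. `sign_mode="fixed"`
applies the scalar uniformly and exists for shift-recovery checks.
Non-signature genes carry no group structure.

`generate_pathway_db` emits random gene sets over a platform universe plus
optional planted pathways sharing a chosen fraction of their members with a
source set (the planted signature in the pipeline), standing in for curated
collections (KEGG/Reactome-style GMT files are read natively, so real
collections drop in unchanged).

What the generator does **not** emulate: array spatial artifacts, batch
effects, probe-level sequence biases, correlated gene modules, and
platform-specific background correction. Passing tests therefore demonstrate
that the statistical machinery is correct and calibrated under a clean
generative model, not that the pipeline is robust to every failure mode of
real microarray data.

## Preprocessing

Input matrices are log₂ intensities assumed already background-adjusted;
platform-specific raw processing (CEL parsing, convolution background
correction, median-polish summarization) is deliberately out of scope.
Quantile normalization maps each column onto the reference distribution
(row means of the column-sorted matrix); ties within a column receive the
mean of the reference values at their tied ranks ("ties = average" dialect —
dialects differ, so this is stated). The operation is idempotent and
rank-preserving; column means agree to 1e-9 after normalization.

One uniform normalization is applied to all studies, including the
non-Affymetrix-style one — per-platform pipelines differed in the original
labs, but the artifact favors one auditable treatment.

Probe→gene collapse keys genes by Entrez ID when present, else by exact
(case-sensitive) MGI symbol: Entrez is unambiguous while symbols drift.
`max_mean` (default) keeps the probe with the highest mean intensity, ties
broken by lexicographically smallest probe ID for determinism; `mean`
averages probes. Unmapped probes are dropped and counted in the log.

## SAM differential expression

The two-class unpaired statistic is d = (x̄₁ − x̄₂)/(s + s₀) with s the
pooled standard error. s₀ is searched over the 21 percentiles
{0, 5, …, 100}% of s, minimizing the coefficient of variation of the median
absolute deviation of d within 100 equal-count windows of s (ties → smallest
candidate; all-equal s degenerates to s₀ = 0 with a warning).

Permutation null: all distinct label assignments when there are at most
`n_permutations` (default 200) of them, else a seeded sample without
replacement that always includes the observed assignment. s₀ is held fixed
across permutations. For each grid Δ (step 0.05 from 0 to the largest
observed gap), the upper cutoff is the smallest observed order statistic
exceeding its permutation mean by more than Δ (symmetric below), and

FDR(Δ) = π₀ · median_b #{permuted d beyond cutoffs} / max(1, #called).

The selected Δ is the smallest with FDR ≤ `target_fdr` (default 0.05); an
empty call set has FDR 0 by convention, so a Δ always exists at the top of
the grid. π₀ defaults to 1 (conservative); mode `"quantile"` estimates
π̂₀ = min(1, #{dᵢ in the 25–75% band of permuted d} / (0.5 · #genes)). The
original analysis does not state its permutation count or π₀ handling, so
both are exposed in `SAMConfig` and recorded in run summaries.

Measured operating characteristics (recomputed by `scripts/acceptance.py`):
under the global null the median number of calls is 0 (20 seeds, 1000 genes,
6 vs 6); with 100 genes planted at 3 SD the median sensitivity and realized
false-discovery proportion are written to the acceptance JSON and sit near
0.99 and 0.05.

## Overlap statistics

The common background is the exact intersection of the harmonized platform
universes; the signature is the intersection of the background-restricted
called sets. The overlap null treats each called set as an independent
uniform fixed-size subset of the background. The 2-way tail is the classical
hypergeometric survival probability; the 3-way tail conditions on
m = |A∩B| (hypergeometric in N, a, b) and sums h(x; N, m, c) over m — exact,
and reducing to the 2-way test at c = N. All tails are accumulated via
log-sum-exp of `scipy.stats.hypergeom.logpmf`, so p-values many hundreds of
orders below double-precision underflow are computed exactly and reported in
log₁₀ alongside linear form. The independence null is the natural k-way
extension of the standard 2-way overlap test; nothing in the source analyses
pins down a different 3-way null. Certain events (t at or below the minimal
feasible overlap) return exactly 1; impossible overlaps return 0 with a
warning. A seeded Monte-Carlo routine covers k > 3 (flagged experimental)
and doubles as an independent cross-check in the tests, alongside bitmask
enumeration oracles for small universes.

Pairwise tests default to per-pair backgrounds (the intersection of the two
platforms' universes), switchable to the common all-study background; the
3-way test always uses the common background. Both frames are recorded in
the report.

## Pathway enrichment and enrichment map

Per study, pathway sets are intersected with that study's platform universe
(the sampling frame actually interrogated) before an upper-tail
hypergeometric test; the historical raw-p ≤ 0.05 rule is retained as the
significance flag, with Benjamini–Hochberg q-values reported alongside.
Note that exact hypergeometric p-values are discrete and therefore
conservative: the achievable size of a 0.05-level test is strictly below
0.05 (about 0.03 under the synthetic collection's geometry), and the null
calibration check in the tests compares observed exceedance against that
exact achievable size rather than against nominal 0.05.

The enrichment map takes each study's top-20 terms, keeps those with raw
p ≤ α in at least one study, and connects retained terms whose
universe-restricted gene sets have Jaccard similarity ≥ 0.25 (the common
enrichment-map convention; the edge rule is not specified by the source
analyses). Node and edge TSVs import directly into network tools.

## Consensus validation

Subsampling is over **features**: each of the `reps` (default 1000)
replicates draws ⌈0.8 · |signature|⌉ signature genes without replacement,
centers each gene to mean 0, and clusters all samples by average linkage on
1 − Pearson correlation, cut at k = the number of exposure groups. Because
every sample pair co-occurs in every replicate, the consensus denominator is
simply `reps`. Item-resampling consensus clustering (where the denominator
is the co-occurrence count) is the other reading of "subsample"; feature
subsampling is the deliberate interpretation here since the procedure
subsamples *the gene signature*, and the mean within-/between-group
consensus values are reported alongside the headline partition-match rate so
both readings of "accuracy" are available.

"Accurate classification" is operationalized as an exact partition match
(adjusted Rand index 1) at k groups; the distance/linkage pair is the
dominant convention for expression heatmaps and is exposed as config
(Euclidean available). Zero-variance sample profiles make Pearson
correlation undefined and raise an error naming the sample. The random
baseline pushes `n_signatures` (default 1000; 200 in the analysis driver,
100 in tests) uniformly drawn gene sets of the same size through the
identical procedure with `reps_per_signature` replicates (default 50) —
desk-scale sizes chosen so the full chain runs in seconds; the comparison is
a direction check and is insensitive to these sizes.

## Determinism and numerics

A single global seed fans out to fixed per-stage offsets (simulate +11,
multicondition +23, pathways +37, SAM +53, consensus +71, baseline +89, all
reduced mod 2³¹−1), so adding a stage never perturbs earlier stages'
randomness. Identical config + seed reproduces every output file byte for
byte (JSON is written with sorted keys; no timestamps in outputs). Merge
ties in the hierarchical clustering are resolved by scipy's deterministic
linkage ordering; `max_mean` probe ties by probe-ID order; s₀ ties by the
smallest candidate.

## Known limitations

- The generator's clean Gaussian, batch-free model means calibration results
  bound what the statistics do under ideal conditions only.
- Quantile normalization redistributes strongly asymmetric (one-sided)
  differential signal across samples and shrinks it; the pipeline's planted
  effects are sign-balanced, where the step is unbiased.
- The exact k-way overlap test is implemented for k ≤ 3; larger k falls back
  to seeded Monte Carlo.
- GO-hierarchy-aware redundancy pruning, rank-based (GSEA-style) enrichment,
  and cross-species ortholog mapping are out of scope.
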