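# Methods

`mutlike` re-implements, as a tested pipeline on synthetic cohorts, a
discovery procedure for a "TP53-mutant-like" subgroup of TP53-wild-type AML:
a cross-cohort expression signature of TP53-mutant disease, single-sample
enrichment projection, clustering-based subgroup calling with bootstrap
validation, and the downstream stratification statistics (isoform ratios,
survival, drug synergy). This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Discovery chain

**Differential expression.** Per gene, a two-sided Mann-Whitney U test of
TP53-mutant versus wild-type samples: exact enumeration when both groups
have ≤ 8 samples, otherwise the tie-corrected normal approximation. Effect
size is the log2 ratio of group means with pseudocount 1 on the linear
scale (log2-scale input is un-logged first). Multiplicity is handled with
Benjamini-Hochberg throughout.

**Signature derivation.** Per cohort, genes with positive log2 fold change
are ranked by fold change and truncated to the top quantile (default 20%);
the signature is the intersection across cohorts. No significance gate is
applied by default: with a strong q-threshold the up-list collapses to the
genuinely shifted genes and a 20% truncation of that list would by
construction discard 80% of the true program, defeating the stated intent
of a "top 20% of up-regulated genes" rule. A `q_threshold` parameter
restores the gate for users who want it. An empty intersection is a valid,
warned result.

**ssGSEA.** For one sample, genes are ranked by expression (rank values
1..N, N = highest; ties share the average rank and order deterministically
by gene ID — determinism is preferred over fidelity to any single existing
implementation). For a gene set S,

    ES = Σ_i [ P_in(i) − P_out(i) ],

where P_in is the cumulative sum of |rank|^α over in-set genes divided by
its total, and P_out the cumulative count of out-of-set genes divided by
N − |S|. The weight exponent α defaults to 0.75 (the ssGSEA projection
convention); scores are reported unnormalized, with optional min-max
normalization over the projected matrix behind a flag. Scores are invariant
to any monotone transform of expression, so linear and log2 input give
identical results. Sets with matrix coverage below `min_set_coverage` are
dropped with a warning.

**Preranked GSEA.** The weighted Kolmogorov-Smirnov running sum over a
signed ranking metric (weight |score|^1 for in-set steps, uniform decrement
otherwise); ES is the signed maximum deviation. When the positive and
negative extremes tie in magnitude to rounding (1e-12), the extreme reached
first down the list is reported — a convention required for bit-level
determinism. The null is gene-label permutation (random sets of matching
size); NES divides ES by the mean |null ES| of matching sign; the nominal p
is the one-sided null exceedance counted over *all* permutations (this is
the definition under which a single top-ranked gene in a list of N has
exhaustive-null p = 1/N); FDR q follows the normalized-exceedance-ratio
procedure over the collection, clipped to [0, 1]. Default significance is
q < 0.25, the conventional preranked-GSEA screen.

**Panel selection.** Per projected gene set, Mann-Whitney on enrichment
scores (mutant versus wild-type status) with BH across sets; sets at
q < 0.05 (configurable) form the clustering panel, annotated up/down.

**Clustering and calling.** Each panel set's scores are z-scored across
samples (the heatmap convention — without row scaling, uniformly shifted
sets carry no profile shape and a correlation distance cannot separate
groups). Sample-sample distance is 1 − Spearman correlation of the z-scored
enrichment profiles; agglomerative clustering uses Ward linkage by default,
cut at k = 2. Ward was chosen after average linkage proved unstable at the
default study conditions: its k = 2 cut intermittently isolates a small
tight sub-cluster instead of splitting along the program axis (observed
planted-subgroup sensitivity as low as 0.28 on one seed), while Ward's
variance criterion yields balanced, reproducible cuts. Linkage and k remain
configurable. The cluster with the highest fraction of status-mutant
samples anchors the call: its wild-type members are labeled mut-like;
status-mutant samples are labeled mut regardless of cluster; a tie in
mutant fraction is an error unless an explicit tie rule is requested.

**Bootstrap validation.** Signature enrichment is resampled with
replacement within label groups (B = 1000): group means with 2.5/97.5
percentile intervals, and for each group pair the apparent mean difference
with a Harrell-style optimism correction (apparent difference minus the
mean excess of bootstrap differences over the apparent one). Fully seeded.

## Stratification statistics

Isoform ratios (e.g. ΔNp73/TAp73) are computed on linear-scale expression
only; samples with a zero denominator are excluded with a warning rather
than imputed. Dichotomization defaults to a median split with ties going
low; upper-quartile and fixed-cutpoint alternatives are recorded in the
output. qPCR quantification uses 2^−ΔΔCt against a housekeeping gene and a
reference sample. Survival uses the Kaplan-Meier product-limit estimator
with Greenwood variance, the log-rank chi-square across groups (df =
groups − 1), and Cox proportional-hazards regression (partial likelihood,
Efron tie handling, Wald intervals) via lifelines; survival time is in
months. Pearson correlation intervals use the Fisher z-transform,
tanh(atanh r ± z/√(n−3)), with the t-test p on n − 2 df. For the reported
r = 0.66 at n = 16 this gives (0.244, 0.871): the upper bound reproduces
the printed 0.87, the lower rounds to 0.24 against a printed 0.25 — the
0.01 discrepancy is noted, not resolved.

## Counts processing

CPM = count / library size × 1e6, with library sizes taken before gene
filtering; log2CPM = log2(CPM + 1) (pseudocount 1). The expressed-gene
filter keeps a gene iff some condition has CPM > 1 (strict) in at least
half of its samples, inclusive for odd sizes (⌈n/2⌉). The filter is
monotone in counts and per-column scale-equivariant.

## ZIP synergy

Monotherapy margins are fitted with a four-parameter log-logistic curve
y(d) = ymin + (ymax − ymin)·d^s/(d^s + m^s), least squares with asymptotes
bounded to [0, 1] and slope to [0.05, 20]; flat data yield a flat-line fit
with a warning. The zero-interaction surface is Bliss independence of the
fitted monotherapy effects, y1 + y2 − y1·y2. Observed combination responses
are smoothed by conditional 4PL refits along each axis with the baseline
anchored at the other drug's fitted effect (the potency-shift idea, in its
two-way conditional-fit form); a failed conditional fit falls back to the
observed responses with a logged flag. δ = 100 × (fitted observed −
expected) percentage points; the ZIP score is the mean δ over combination
wells (both doses > 0). Classification: > +10 synergistic, < −10
antagonistic, boundaries inclusive of additive. Responses are inhibition
fractions in [0, 1]; % viability input must be converted by the caller.

## Synthetic data: what it emulates, and what it does not

The cohort generator plants the structure the pipeline assumes: log-normal
expression (log2 values Normal(μ_g, 1), gene baselines μ_g ~ Normal(8, 2));
a 100-gene program shifted up by 1.5 SD in mutant and mut-like samples;
10% mutant samples and a hidden mut-like subgroup of 22% of the wild-type;
exponential survival with hazard ratios 3.0 (mut) and 2.0 (mut-like)
versus wild-type (median wild-type OS 24 months) under uniform censoring
over a 120-month window (~25–30% censored); two-cohort runs draw
independent gene baselines but share the program. Gene-set panels emulate a
heatmap panel in which the sets are mutually correlated and differentially
enriched: by default for end-to-end runs, the derived signature plus 30
random program subsets plus 34 pure decoys (65 sets); pure-decoy panels
remain available for null-calibration tests. Isoform tables are log-normal
with a four-fold higher ΔNp73/TAp73 geometric-mean ratio in planted
samples; counts are negative binomial (dispersion 0.1) with planted fold
changes; dose grids follow declared 4PL margins under a Bliss-null or
planted-excess regime. The default dose-response curves have partial
efficacy (Emax 0.60/0.55) so that a planted +0.15 combination excess
survives the [0, 1] response clip instead of being truncated at saturating
doses.

Deliberately not emulated: real cohorts' marginal expression distributions,
batch structure, mutation co-occurrence, gene-gene correlation beyond the
planted program, or informative censoring. Passing recovery tests therefore
demonstrates correctness of the machinery under the assumed generative
structure, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

Duplicate gene rows collapse by per-gene maximum (logged). Expression scale
is declared by the caller, never guessed. All-constant samples rank
lexicographically with a warning; constant enrichment profiles make
Spearman undefined and raise an error naming the sample. An empty signature
intersection, an all-censored survival group, and a flat dose-response
margin are all defined, non-fatal results; a cohort with no mutant samples
(no anchor cluster), perfect separation in Cox regression, and an all-zero
ratio denominator are errors. Every stochastic step takes an explicit seed
and is bit-reproducible; double-run identity is part of the test suite.

## Problem sizes

Default synthetic studies use 200 samples × 2,000 genes per cohort with a
100-gene program and a 65-set panel; recovery checks in the acceptance
script average over three replicate studies, and survival calibration uses
100 replicates of n = 500. These sizes give stable operating
characteristics (planted mut-like sensitivity/specificity ≈ 0.95 on
average) while keeping a full run in well under a minute per stage.

## Known limitations

The 65-set panel of the original analysis was curated from ~34,550 MSigDB
sets by an unstated rule; the package adopts a BH-screened Mann-Whitney
selection and treats the panel as data. The optimism correction is the
simple Harrell bootstrap on group-mean differences. No consensus
clustering, mixture-model calling, batch correction, competing risks,
time-dependent covariates, or maximally selected cutpoints are provided;
phenotype-permutation GSEA and leading-edge reporting are out of scope.
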