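# Methods

This note records the modeling choices behind `toxsig`: what each stage
assumes, which parameters matter and why their defaults were chosen, what
the synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Labels and data preparation

Samples are labeled binary. In vitro experiments use LDH activity (%): a
value strictly above 105% or strictly below 95% is "dysregulated";
values exactly at a cut-off are "non_dysregulated" (the decision rule is
strict inequality, so the normal band is closed). Mid-range samples are
labeled non_dysregulated rather than excluded — the non-dysregulated class
is defined as controls plus exposures without toxic outcome, and a total
labeling keeps cross-validation folds well-defined. In vivo experiments use
the five-level ordinal histopathology scale; {present, minimal, slight} map
to non_dysregulated and {moderate, severe} to dysregulated. A dataset is
labeled from exactly one endpoint; carrying both annotations on a sample is
an error rather than a silent priority rule.

Duplicate gene rows are averaged per sample with missing entries ignored
per cell. Ortholog harmonization is deliberately conservative: case-folded
symbol identity only (rat `Ddr1` ↔ human `DDR1`), no homology tables;
unmatched genes are dropped. Missing values are preserved (not imputed)
through this layer — the correlation stage handles them pairwise, and the
random-forest layer mean-fills per gene only at matrix-construction time,
the least informative single-value choice.

## Consensus co-expression network

Hard thresholding at |r| ≥ 0.6 on pairwise-complete Pearson correlation,
with at least 3 shared observations per pair (below that a correlation is
meaningless and no edge is formed). The threshold applies to the absolute
value and edge weights are |r|: strong negative co-expression is as
informative as positive for module membership. A `signed` flag restricts
edges to positive correlations for users who want signed modules.
Zero-variance genes stay in the node set but form no edges (r is undefined).

The consensus keeps only edges present in every per-dataset network and
averages their absolute correlations. This intersect-then-average rule makes
the consensus weight bounded by the per-dataset min/max, and makes the edge
set exactly the set-intersection of the inputs — both properties are tested
against direct set algebra. Genes that lose all edges remain as isolated
nodes and later become singleton clusters rather than being dropped.

No soft-thresholding / scale-free fitting is attempted: the procedure is a
hard-threshold consensus by design.

## Prior knowledge

Features per gene: one z-scored 0/1 membership indicator per gene set
(z-scored per feature across the gene universe — the standard reading of
"transform indicators into z-scores"; a constant column cannot be z-scored
and is zeroed with a warning), plus degree, betweenness and closeness
centrality on the mechanistic/marker subgraph of the typed interaction
graph ("therapeutic" associations are excluded as toxicologically less
relevant). Topology features are transformed log(1 + x): a log without
offset is undefined for the many zero-degree genes. Betweenness is
normalized (flag to disable); closeness uses the standard
reachability-corrected formula so disconnected graphs are well-defined. At
reference scale (50 hallmark-like + 186 kegg-like sets) the vector has 239
dimensions.

Prior scores: PCA to two components, K-means with K = 3 (10 seeded
restarts, Lloyd iterations, tolerance 1e-6), raw score = Euclidean distance
to the gene's *assigned* centroid — genes far from their cluster core are
the annotation-rich outliers the prior is meant to up-weight. Distance to
the assigned centroid (not the minimum over all centroids) is used because
the outlierness of a gene is relative to the cluster that claims it. Raw
scores are ranked descending, ties broken lexicographically by symbol for
determinism, and rank r of n maps to P = (n − r + 1)/n, giving exactly 1.0
at the top and 1/n at the bottom. The mapping is a bijection from ranks, so
priors are strictly positive and permutation-equivariant under relabeling.

## Re-weighting and Markov clustering

Default re-weighting is S·(P(A)+P(B))/2; the product form S·P(A)·P(B) is
available as `mode="product"`. The mean form is monotone in each prior and
is the identity when all priors are 1 — both are regression-tested.

The Markov Cluster Algorithm is implemented from scratch on a dense
column-stochastic matrix: self-loops (weight = each node's maximum incident
edge weight, the standard choice that keeps loop flow commensurate with
edge flow), then alternating expansion (matrix power, default 2) and
inflation (entrywise power, default 3.3, followed by column
renormalization) with pruning of entries below 1e-5 (a column's maximum is
never pruned), until the maximum entrywise change drops below 1e-8 or 200
iterations. Columns are renormalized after every operation, and a test
spies on the normalization to assert every column sums to 1 ± 1e-9
throughout. Clusters are the attractor basins of the limit matrix;
attractor systems with overlapping basins are merged, and a gene attracted
by several systems goes to the one holding the largest share of its column
mass (ties to the lowest cluster index), so the output is always a strict
partition. Non-convergence at the iteration cap returns the current
interpretation with a `converged=False` flag and a warning. The
implementation is checked for exact partition equality against an
independently written reference MCL on dozens of random weighted graphs.

Quality metrics for inflation selection:

* mass fraction = (intra-cluster edge weight) / (total edge weight);
* efficiency = mean over nodes of cov(v) · (1 − (|C(v)| − 1)/(n − 1)),
  where cov(v) is the fraction of v's incident weight kept inside its
  cluster (1 for edgeless nodes). This is a coverage score penalized by
  cluster spread in the spirit of the clustering-performance measures
  used with the original MCL tooling: a single all-inclusive cluster has
  perfect coverage but efficiency 0, all-singletons on a connected graph
  have efficiency 0, and compact well-separated clusters score highest.

The inflation scan tabulates cluster counts, both quality measures and
size summaries (mean size = genes/clusters) over a list of inflation
values; cluster counts weakly increase with inflation on modular graphs.
No post-processing is applied to large clusters.

## Gene selection

One random forest per cluster (500 trees, √p features per split — common
defaults for expression data), stratified 5-fold CV; accuracy is the mean
fold accuracy and importances are Gini importances averaged over folds.
Accuracy (not GMean or F1) weights the quota, matching the definition of
the allocation rule. The budget is apportioned as total·acc_c/Σacc,
integerized by largest remainder (which reproduces 522/478 for
{60%, 55%} and 1000 and guarantees exact totals), capped at cluster size,
with capped excess redistributed proportionally among uncapped clusters
until the budget is met or all genes are allocated; all-zero accuracies
fall back to size-proportional allocation with a warning. Within a cluster
the top-quota genes by importance are taken (ties → higher fold-stability,
then symbol). A final forest over the assembled genes produces the global
ranking; it re-ranks only and never drops or replaces genes, which makes
smaller and larger panels exact nested prefixes of one ranking. Regulation
is "up" iff mean expression in dysregulated samples exceeds that in
non-dysregulated samples on the primary training dataset.

## Evaluation

Metrics follow the standard confusion-matrix formulas, with every 0/0
ratio defined as 0 so degenerate folds cannot produce NaNs. GMean² =
sensitivity·specificity holds to 1e-12 on exact counts. The default
classifier panel is {LDA, NBC, QDA, DT, RF}; KNN (K = 3) is registered and
selectable, so both historically used panels are available. LDA and QDA
use shrinkage-regularized solvers because gene sets routinely exceed the
per-class sample count and unregularized class covariances would be
singular. Out-of-fold predictions are pooled into one confusion matrix per
classifier before metrics are computed — at small n, per-fold metrics are
high-variance and pooling is the stabler choice (`pool_folds=False`
restores per-fold averaging). Folds are stratified.

The random baseline draws uniform gene sets of matched size and evaluates
each identically. Significance uses Welch's unequal-variance two-sample
t-test per metric on per-classifier average scores (5 values per side with
the default panel), α = 0.1; no multiple-testing correction is applied
across metrics, which are reported raw. A seeded calibration test confirms
the type-I error is within ±0.05 of nominal over 1,000 null replicates.

## Benchmark dose

Genes enter curve fitting only after a classic (equal-variance) one-way
ANOVA across dose groups with Benjamini–Hochberg FDR ≤ 0.05. The model
suite (exponential degrees 2–5, polynomial 2–3, linear, power, Hill) is
fit by least squares; parameterizations are documented in `bmd.py`. The
Hill exponent and the power/exponential shape exponents are bounded below
by 1 to avoid super-sensitive low-dose artifacts from fractional
exponents. AIC = n·ln(RSS/n) + 2k; non-converged fits are excluded rather
than penalized with infinite AIC, and near-ties (within 1e-6) break toward
fewer parameters. The benchmark response is a 10% *absolute relative*
change from the fitted control level, |f(d) − f(0)| = 0.1·|f(0)|, so
down-regulated genes are covered; the BMD is the smallest positive
crossing within the tested dose range, solved in closed form for the
linear (0.1·|f(0)/b|) and power models and by grid-bracketed root-finding
otherwise. AIC selection is invariant to dose-unit rescaling and the BMD
rescales linearly (tested).

Group-level BMD_t: pathways enriched in BMD-bearing genes by one-sided
Fisher's exact test (p < 0.05) against the background of all genes that
entered the ANOVA filter, then filtered to strictly more than 3 BMD-bearing
members and strictly more than 5% membership coverage; each passing pathway
is scored by its mean member BMD and the minimum score is BMD_t, undefined
when nothing passes. Concordance with apical BMD_a reports the number of
defined pairs, the mean BMD_t/BMD_a ratio, and the Pearson correlation of
log10 pairs (benchmark doses span orders of magnitude; a linear-scale flag
exists). Confidence limits (BMDL/BMDU) and model averaging are out of scope.

## Synthetic data: what it emulates and what it does not

The generator plants a single latent factor per module: gene i in module m
is √ρ·F_m + √(1−ρ)·ε, giving expected pairwise correlation exactly ρ
within the module in every dataset — the simplest construct with a
controllable correlation target (verified by Monte-Carlo to ±0.05 at
ρ = 0.9). Genes of the informative modules are additionally shifted by the
label effect size in dysregulated samples; LDH values and histopathology
grades are then drawn consistently with the latent label so the labeling
code path is exercised end to end. Missingness is completely at random —
only overall missing percentages are being emulated. Rat-style datasets
carry title-case symbols to exercise harmonization.

Defaults define the study conditions at desk scale: 600 genes in 10
modules of 60 (the whole universe is module-structured; background-only
genes are available by shrinking `module_sizes` and appear as singleton
clusters), 120 samples per dataset, within-module correlation 0.8, 3
informative modules, effect size 1.5 SD, 30% dysregulated (balanced enough
for stratified 5-fold CV while keeping dysregulation the minority
outcome), 10% missing values, 40 gene sets with enrichment odds 5 toward
informative genes, an interaction graph with degree skew toward
informative genes and 20% therapeutic edges, and a 6-level dose design
(0–4, triplicates) where 40% of 120 genes respond along Hill curves whose
10%-change dose equals a planted log-uniform benchmark dose (the planting
is exact by construction: the Hill half-maximal dose is solved from the
target BMD).

Passing tests on these fixtures demonstrates the pipeline's correctness
and its recovery behavior under the planted model; they do not demonstrate
performance on real microarray data, which has probe- and batch-level
noise structure, non-Gaussian intensity distributions, unbalanced designs
and imperfect orthology that the generator deliberately omits.

## Numerical and degenerate-input conventions

Pair correlations need ≥3 complete observations; constant genes warn and
form no edges. K-means on identical feature rows yields all-zero distances
and the lexicographic tie-break produces a deterministic, still-bijective
score ladder. MCL on an edgeless gene yields a singleton. Quota allocation
with budget ≥ capacity returns every cluster in full. Confusion ratios
0/0 are 0. Curve fits that fail to converge are recorded and skipped; a
flat winning fit yields an undefined BMD with a reason code, as does a
zero control level. All randomness flows from explicit integer seeds; the
CLI fans one global seed into per-stage seeds via SHA-256 so stages are
independently reproducible.

## Problem sizes

The shipped tests and examples run the pipeline at the desk scale above —
hundreds of genes, tens of clusters — chosen so the full suite exercises
every stage, including the end-to-end selection recovery, in a few
minutes on one CPU. The algorithms are dense-matrix implementations;
networks of ~10⁴ genes would need sparse expansion and
pruning strategies that are out of scope here.

## Known limitations

* Ortholog matching by symbol identity misses true orthologs with
  divergent symbols and can conflate paralogs that share one.
* Dense MCL limits practical network size (~a few thousand genes).
* Gini importances are biased toward correlated feature groups; within a
  co-expression cluster this is partly by design (any module
  representative is acceptable) but ranking within near-duplicate genes is
  seed-sensitive.
* The efficiency measure is one defensible coverage/spread trade-off among
  several used with MCL tooling; inflation choices should be read from the
  whole scan table, not from efficiency alone.
* The t-test against the random baseline treats per-classifier averages as
  independent observations; with five classifiers this is a coarse
  approximation, mirrored from the evaluated protocol.
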