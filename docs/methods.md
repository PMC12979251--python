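# Methods

This note describes the models and procedures implemented in `cpibind`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmarks do and do not demonstrate.

## 1. Hashtag demultiplexing (`cpibind.tags`)

Pooled samples are labeled with per-sample hashing antibodies (HTOs); the
demultiplexer assigns each droplet a sample of origin and flags
cross-sample doublets.

**Procedure.** Tag counts are CLR-normalized per cell
(`y_ij = ln(x_ij+1) − mean_k ln(x_ik+1)`, mean over the tag panel only, so
rows sum to zero).  An initial partition is obtained with CLARA-style
k-medoids (`k = n_samples + 1`, Euclidean distance on CLR values, PAM
alternation on a ≤1000-cell subsample with 8 seeded restarts, best total
cost kept).  For each tag, a negative binomial (mean/shape
parameterization; method-of-moments start, profile-likelihood refinement of
the shape) is fitted to the raw counts of the tag's *negative* cells, and
the positive threshold is the NB quantile at `positive_quantile` (default
0.99).  A cell positive for exactly one tag is a singlet; for several, a
doublet; for none, negative.

**Negative-sample rule.** The negative cells for a tag are those in every
cluster whose mean raw tag count lies below the log-midpoint between the
lowest and highest cluster means.  Excluding only the single highest-mean
cluster fails when the clustering splits one tag's positives across two
clusters (the leftover positives then contaminate the NB fit); fitting only
the single lowest-mean cluster fails when the pool has no sizeable
negative population (the fallback sample is then a truncated quintile and
the threshold collapses).  The log-midpoint rule excludes *all* high
clusters and is robust to both failure modes; the convention is recorded in
`DemuxResult.metadata`.  Raw counts (not CLR values) are fitted because the
threshold must live on the count scale.

**Monotonicity.** Raising `positive_quantile` raises every NB threshold,
so no cell's positive-tag count can increase — doublet calls shrink
monotonically.

## 2. Drug-occupancy calling (`cpibind.binding`, `cpibind.qrf`)

**Biology and model.** Therapeutic anti-PD-1 antibodies occupy the same
epitope the CITE-seq detection antibody binds.  An occupied (CPI-bound)
cell therefore yields fewer PD-1 ADT counts than its state would predict,
while *PDCD1* mRNA is untouched.  The caller learns, from untreated cells
only, the conditional distribution of the CLR PD-1 tag signal given
drug-blind covariates: up to 30 batch-integrated embedding components,
cell-cycle scores and phase, reaction identity, total RNA counts, gene
detection rate, mitochondrial and ribosomal percentages, and normalized
PDCD1 mRNA (log1p of library-size-scaled counts).

**Feature selection.** Recursive elimination: fit a random forest, compute
permutation importances (clipped at zero, rescaled to sum to 100), drop the
single weakest feature, refit, until every surviving feature holds at least
5% of total importance (`importance_threshold = 5`).  The 100-point scale
is the natural reading of a threshold of 5 for an otherwise scale-free
importance measure.

**Quantile regression forest.** A random forest regressor whose leaves
retain their training targets.  The conditional CDF at a query x is the
average over trees of the fraction of leaf targets ≤ y; conditional
quantiles are the type-1 inverse of that single per-query CDF, hence
monotone in τ by construction; conditional sampling inverts the merged
leaf ECDF at uniform variates.  Ties use the weak inequality (≤), so a
measurement equal to the conditional minimum gets u > 0 and is not
automatically called bound.  Defaults: 300 trees, `min_samples_leaf = 20`,
all features considered per split.  The split setting was fixed by a
dedicated calibration study (untreated cells, 5000 train / 2000 held out,
six probe seeds): fully greedy splits minimize the worst-case deviation of
P(u < α) from α (0.018 vs 0.026 for mtry = p/3), because greedier trees
produce more homogeneous leaves and less over-dispersion of the estimated
conditional distribution.

**Decision rule.** A treated cell is called bound at confidence α iff
`u = F̂(measured | x) < α`, one-sided lower tail: competitive epitope
blocking can only *suppress* the measured tag.  The default ladder
α ∈ {0.01, 0.05, 0.10, 0.15} corresponds to predicted-quantile thresholds
0.99/0.95/0.90/0.85; bound sets are exactly nested across α because they
threshold the same u.

**Validation splits.** One untreated donor is held out entirely (an
independent control set) and 33% of the remaining untreated cells form a
random hold-out; Pearson r between the predicted median and the measured
signal is reported for both.

**Per-cluster fractions.** The point estimate is the fraction of a
cluster's treated cells bound at α.  The accompanying interval resamples
every cell's hypothetical measurement from its model conditional
distribution (200 seeded draws), re-calls bound status and takes the
2.5/97.5 percentiles of the per-draw fractions.  Because the conditional
distribution describes *unoccupied* signal, this interval is the band of
fractions expected if the cluster behaved like untreated cells (≈ α); an
observed fraction far above the band is evidence of genuine occupancy.  A
Wilson binomial interval is reported instead when no conditional draws are
supplied, and the `ci_method` column says which was used.

## 3. Spatial receptor–ligand co-localization (`cpibind.spatial`)

**Score.** For location i and pair (L, R):
`S_i = (Σ_j d_j L_j / n) · (Σ_j d_j R_j / n)`, where the sums run over all
locations with positive weight, `d_j = 1 − dist_ij / (cutoff·(1+1e−6))`
(linear in distance, ∈ (0, 1], zero beyond the cutoff), the focal location
contributes with weight 1, and n counts the nonzero-weight locations so
edge-of-tissue neighborhoods are not penalized.  The default cutoff is two
lattice rings (2 × pitch); cell-resolution maps use the same machinery
with a micron radius per FOV.  Weights are computed per slide — no
cross-slide smoothing.

**Null and inference.** Expression profiles are shuffled across locations
within each slide (profile-preserving, so gene–gene correlation survives
under the null) and all scores recomputed; default 100 permutations.  The
null is pooled across locations and slides per pair; per-location nulls are
available behind `per_location_null=True`.  Empirical p-values use the
add-one rule `p = (1 + #{null ≥ obs}) / (1 + N_null)` and never return
zero.  Benjamini–Hochberg correction is applied jointly across all tested
(location, pair) combinations, and locations with FDR < 0.05 are positive.

**Enrichment.** For each group (region cluster or condition) and each pair
positive in at least one location of that group, a Gaussian linear model
`score ~ is_group + detection_rate` is fitted over all locations; the
group coefficient and its p-value are reported with BH correction across
pairs × groups.  Blocking on per-location gene detection rate absorbs
capture-efficiency variation.

**Neighbor-class comparison.** Locations are classed by their neighborhood
content within the weight cutoff (self excluded): near a CPI-bound T cell,
else near another T cell, else other; per-class median/IQR and pairwise
two-sided rank-sum tests compare a local score (e.g. an IFNγ signaling
score) across classes.

## 4. Niches and tissue networks (`cpibind.niches`)

**Neighbor composition.** For every cell the types of its immediately
adjacent neighbors are counted, self excluded, within the cell's FOV.
"Immediately adjacent" defaults to mutual k-nearest neighbors (k = 10)
with a 30 µm radius cap; Delaunay triangulation with the same cap is
available behind `rule="delaunay"` since segmentation-contact adjacency is
not otherwise recoverable from centroids.

**Niche clustering.** Composition rows are proportion-normalized, reduced
by PCA (10 components), embedded in a k-NN graph and partitioned by Leiden
modularity optimization at resolution 0.7.  The graph uses 50 neighbors:
composition vectors are low-dimensional and heavily tied, and sparser
graphs fragment planted niches into dozens of micro-communities (ARI
dropped from ~0.9 to ~0.45 at 15 neighbors on the planted benchmark); the
resolution itself is kept at the cell-clustering default.

**Crypt-top adjacency networks.** Spots with crypt-axis score > 1.0
(crypt-top layer) are kept; for each focal spot the adjacent spots
(0 < dist < 4 in the map's units, diagonal neighbors included by
construction) are tallied by region cluster, and the mean per-cluster
fractions over each source cluster's focal spots become directed edge
weights.  Self-loops are kept; spots without in-window neighbors are
excluded from the means, so outgoing weights sum to 1 whenever all
neighbors are labeled.

**Co-occurrence networks.** Within each condition, Pearson correlations of
per-location cell-type probability scores over all type pairs; edges are
kept when positive, r ≥ 0.15 and p < 0.01 (t-distribution p-value for
Pearson r); constant score columns are excluded with a warning.

## 5. Synthetic data (`cpibind.simulate`)

All count noise is negative binomial NB(μ, θ) with variance μ + μ²/θ,
drawn as a gamma–Poisson mixture; identical config + seed gives identical
output.

**CITE-seq generator.** Each cell carries a latent PD-1 propensity,
lognormal around its cluster mean (defaults: five clusters on a geometric
ladder 0.25–4 expected PDCD1 UMI, σ = 0.5 on the log scale,
mean-preserving).  PDCD1 mRNA ~ NB(propensity·size factor, θ = 10); the
PD-1 ADT count ~ NB(25·propensity·ε, θ = 10) with ε = 0.125 for bound
cells and 1 otherwise — so binding suppresses detection 8-fold without
touching mRNA, and at fixed propensity the mRNA distributions of bound and
unbound cells are identical by construction.  Treatment is assigned at
donor level (8 donors by default); bound cells occur only among treated
cells (probability 0.3 per cluster).  The embedding is cluster centroid +
isotropic Gaussian noise with the first component linearly loaded on log
propensity (loading 1.5), so the forest has signal beyond PDCD1 mRNA.  QC
covariates (total counts, detection rate, mito/ribo percentages) are
computed from the realized count matrix, not drawn independently.  A
4-tag ADT panel (PD-1 + three cluster-modulated controls) makes the CLR
transform meaningful.

**Hashtag generator.** Singlets express one tag at `mu_pos` (default 500)
and the rest at `mu_neg` (10); doublets are sums of two singlet draws from
distinct samples, matching droplet superposition.  The background
dispersion default is θ = 50 (near-Poisson): a 99th-percentile threshold
rule with three negative tags per cell caps expected singlet accuracy at
(1 − sf(q₀.₉₉))³, which only clears 98% when the background is close to
Poisson — i.e. a well-stained pool; strongly overdispersed backgrounds
make that operating point unreachable for any threshold estimator.

**Spatial generator.** Hex (offset rows) or square lattices with
center-to-center spacing = pitch, optional coordinate jitter for cell-map
emulation; i.i.d. NB expression with lognormal per-gene base means; each
planted receptor–ligand pair multiplies both genes' means by its
fold-change inside a circular microdomain (overlapping regions that
disagree about a shared gene are rejected); optional vertical niche bands
assign niche labels and niche-specific cell-type proportions (anchor type
probability 0.7).

**What the generators do not emulate.** Real transcriptome structure,
ambient RNA and index hopping, batch chemistry, segmentation errors,
within-sample doublets, anisotropic tissue geometry, or spatially varying
detection efficiency.  Passing benchmarks therefore demonstrate the
statistical machinery — calibration, oracle equivalence, recovery under
the stated noise model — not robustness to every artifact of real data.

## 6. Benchmark studies (`cpibind.experiments`)

Problem sizes were chosen as the smallest that give the statistics room to
operate: 200-location random maps for oracle equivalence; 500 hex spots ×
20 pairs × 5 seeds for null calibration; a 100×100 hex slide (10,000
spots) with one 7-location, 5-fold microdomain per tested pair (10 pairs)
for recovery — a small domain on a large slide keeps the permutation null
clean, and one microdomain per pathway mirrors a tissue with several
active signaling programs while giving BH a realistic discovery set;
7000-cell CITE-seq experiments (5000 train / 2000 held out for
calibration; ~2000 treated cells, 30% bound, ε = 0.125 for recovery);
2000-cell 4-sample pools for demultiplexing; 100×100 jittered cell maps
with 5 planted niches for niche recovery.

## 7. Known limitations

* QRF conditional CDFs are slightly over-dispersed when covariates explain
  little of the target's heterogeneity, which makes tail calibration
  conservative; feature selection mitigates this and the calibration
  benchmark quantifies the residual error (≤ 0.02 absolute).
* The pooled permutation null is contaminated by truly co-localized
  locations; with very small positive regions on small slides this makes
  the test conservative.  This is inherent to shuffle-everything nulls.
* The per-cluster occupancy interval is a null band, not a bootstrap CI of
  the observed fraction (see §2).
* K-medoids demultiplexing assumes the pool contains each sample at
  reasonable frequency; pools dominated by one sample may need the
  quantile fallback.
* Graph layouts for network visualization are aesthetic only and carry no
  statistical meaning.
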