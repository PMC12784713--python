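# Methods

This note documents the models and procedures implemented in
`methylstruct`, the defaults and why they were chosen, the numerical
details that affect results, and what the synthetic tests do and do not
demonstrate.

## Normalization and transform

Methylation level is quantified as reads per million:
`RPM = counts / library_size × 10⁶`, applied exactly per cell with no
additional scaling or per-site coverage filter.  Empty cells in input
files are errors, never imputed zeros — the upstream methylRAD pipeline
emits explicit zeros for uncovered sites, and silent imputation would bias
the presence/absence component of IndVal.

Before ordination each individual profile is Hellinger-transformed
(square root of row-relative values).  Columns are then centered but not
scaled to unit variance: the transform already places all markers on a
common [0, 1] scale, and unit-variance scaling would inflate near-constant
markers.  Zero-variance markers are dropped before PCA (logged) and carry
zero loadings thereafter, which keeps the identity
`X_centered · marker_loadings = scores` exact on the full marker set.

## DAPC

PCA is computed by SVD of the centered matrix; component signs are fixed
by making each component's largest-magnitude loading positive, so results
are deterministic.  Exactly K−1 components are retained for the
discriminant step (K = number of groups); when the matrix rank is lower —
routine in small fixtures and in small marker subsets — the rank is
retained instead with a warning.

The discriminant step is canonical LDA: the generalized symmetric
eigenproblem of the between-group covariance against the pooled
within-group covariance on the retained PCs, with equal priors (site sizes
are near-equal by design; priors proportional to n would add artifacts).
Axes are normalized so the pooled within-group covariance is the identity
in discriminant space, making classification nearest-centroid.  The
within-group covariance receives a ridge of 1e-8 × its mean diagonal, as
small groups on K−1 PCs can be numerically singular.

Reassignment accuracy is resubstitution by default (refit-free
reassignment of the training individuals), matching the conventional DAPC
summary; a stratified cross-validation mode is available
(`assignment_accuracy(..., method="cv")`).  Resubstitution accuracy on
K−1 retained PCs is substantially inflated by overfitting — on
exchangeable data with two groups of 10 it averages far above the 50%
chance rate — which is why accuracy is interpreted against a
permuted-label baseline in the tests, never against nominal chance.

Per-axis group effects are one-way linear-model F-tests with
Benjamini–Hochberg step-up across the retained axes; axes with q < 0.05
are "significant".  Constant axes get p = 1 and a degeneracy flag.

## Marker ranking and the minimal informative set

Each marker's loading vector across the significant discriminant axes
(switchable to all axes) receives a squared Mahalanobis distance from the
bulk of markers, using the classical mean/covariance across markers.
P-values come from the χ² upper tail with df = number of axes — the
standard reference for Mahalanobis outlier detection — and BH FDR < 5%
flags the discriminant markers.  If no axis tests significant, the ranking
falls back to all axes with a warning.

DAPC is refitted on nested top-ranked subsets over a subset-size grid and
segmented (continuous piecewise-linear) regressions with 1–25 breakpoints
are fitted to the accuracy curve; `AIC = n·ln(RSS/n) + 2·(2 + 2b)` counts
intercept, base slope, and one slope-change plus one location per
breakpoint, and the lowest-AIC model's first breakpoint defines the
minimal set (rounded up to the nearest evaluated grid size — conservative
inclusion).  The breakpoint optimizer is Muggeo-style iterative
linearization with damped updates from quantile-spaced starts (10 seeded
restarts); for one or two breakpoints an exhaustive midpoint grid search
runs first and is then polished, which makes the low-b fits effectively
exact.  With fewer than four curve points no breakpoint is identifiable
and the pipeline keeps all significant markers instead.

**Grid choice.** The default subset-size grid is evenly spaced with step
`max(10, n_significant/40)`.  A grid that samples below ~10 markers lets
the segmented fit resolve the curvature of the first few subset sizes,
where accuracy rises with the retained-PC dimension alone (the rank grows
with the subset until it hits K−1) and with first-coverage of each
cluster; the AIC-best model then places its first breakpoint in the single
digits regardless of how many informative markers were planted, which
defeats the minimal-set interpretation.  A proportional grid measures the
curve on the scale on which the breakpoint is read.  The grid is a
configuration parameter (`grid_min_step`, `grid_target_points`).

## Site clustering

Sites are represented by the unweighted centroid of their individuals'
scores on the retained axes of the minimal-set DAPC refit, with plain
Euclidean distances (no eigenvalue weighting — score space is used as-is).
UPGMA is implemented directly (O(n³), fine for tens of sites) with a
deterministic tie rule: on exact distance ties the lexicographically
smallest cluster-id pair merges first.  scipy's average-linkage serves as
an independent cross-check in the tests.  For each candidate k in
2..(n_sites−1) the tree is cut and the partition coded as a binary matrix
with 1 for between-cluster pairs, so its Pearson correlation with the
distances is positive for structure-respecting partitions; the k
maximizing the correlation wins, ties going to the smaller k (parsimony).
Both extremes are excluded because a constant binary matrix has undefined
correlation.

## IndVal and Jenks classification

IndVal uses the original Dufrêne–Legendre form with no group-size
correction: specificity `A(j,g)` is the share of marker j's group-mean
abundance concentrated in g, fidelity `B(j,g)` the fraction of group-g
units with non-zero abundance, and `IndVal = A·B·100`.  Abundance is raw
RPM (IndVal is an abundance index; the Hellinger transform is an
ordination device) and the sampling unit is the individual, in both the
site-cluster and de novo analyses; site-level units are available as an
option.  Presence means RPM > 0 exactly — in methylRAD, absence is zero
coverage of the site.

Per marker, a one-break Jenks classification of its IndVal values across
groups is computed by exhausting all ordered splits (prefix-sum
vectorized); ties go to the smaller upper class, and markers with
identical IndVal in every group are characteristic of no group.  No
significance test is attached — testing markers selected for their group
contrast against that same contrast would be circular.

## De novo grouping

K-means (50 restarts, k-means++ from a seeded stream, tol 1e-6) runs on
**all** principal components, and k is selected by the spherical profile
form `BIC = n·ln(WSS/n) + k·ln(n)`, ties to the smaller k.  The dimension
matters for this criterion: splitting pure noise reduces the remaining WSS
by roughly 0.36/d per extra cluster, so in low dimension the n·ln(WSS/n)
term always beats the ln(n) penalty and k inflates, while with d on the
order of n (all PCs of an individuals × markers matrix) noise splits fall
below the penalty and the criterion has a genuine interior minimum.
Clustering on all PCs also loses no information.  The PCA scree elbow
(maximal perpendicular distance to the first-to-last chord, reported as
the component before the kink) is advisory metadata; when it disagrees
with BIC, BIC wins and the disagreement is logged.

The second DAPC uses the de novo labels with the same K−1 rule; all K−1
axes are kept internally and the discriminant-eigenvalue scree elbow gives
the number of components to report.

## Gene assignment and enrichment

GFF3 annotations are read through gffutils.  A marker inside exactly one
gene body is assigned to it (exon if within an exon interval, else
intron); markers inside overlapping genes are dropped — only single-hit
loci are kept.  Intergenic markers link to the nearest gene when the
distance to its body boundary (not the TSS) is ≤ 5 kb; equidistant ties
are dropped.  Enrichment per term is the one-sided Fisher exact
(hypergeometric tail) test on the study-set/term 2×2 table, with BH across
terms; a term is enriched when q < 0.05 and it is represented by at least
three study genes.  The universe defaults to all genes with at least one
term (overridable); no term-graph propagation is applied.

## Synthetic data: what it emulates and what it does not

Counts are negative-binomial (gamma–Poisson, shape 0.8) around
`baseline × multiplier × library factor`, with excess zeros from a dropout
probability (default 0.2) and log-normal library sizes around 2.7M reads —
matching sparse, overdispersed methylRAD tag counts.  Defaults follow the
emulated design: 30 sites × 10 individuals; 5000 markers stands in for a
million-site assay at desk scale.  Differentiation is planted in two
tiers, reflecting the effect-size continuum of real methylomes: a small
strongly informative set (1% of markers, log2 fold change `effect_size`)
and a larger weakly differentiated background (8% at 2.5 log2 ≈ 5.7-fold,
detectable at n = 300 but contributing little assignment accuracy).  Site
clusters and within-site latent states can be planted simultaneously and
orthogonally, reproducing the contrast between geographic structure and
cross-cutting methylation groups.  Informative markers are CCWGG-labeled
with probability 0.7 against a 0.52 background, mirroring the non-CpG
enrichment among discriminant markers.

Not emulated: spatial autocorrelation among sites, marker–marker
correlation (co-methylation), per-individual batch effects, mapping
artifacts, and any genotype–methylation linkage.  Passing recovery tests
therefore shows the pipeline correctly inverts its own generative
assumptions at the stated effect sizes — not that real data meet those
assumptions.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic stage is bit-reproducible given the seed.
- Axis and component signs: largest-|loading| positive.
- Ties: Jenks → smaller upper class; UPGMA → lexicographic pair; argmax
  correlation and argmin BIC → smaller k.
- Degenerate inputs: all-zero RPM rows are errors naming the individual;
  all-equal Jenks inputs mean "characteristic of no group"; constant
  discriminant axes get p = 1; singular covariances are ridge-regularized
  with warnings.
- Problem sizes in the test-suite simulations (2000 markers, 300
  individuals; 20 seeds for clustering recovery, 200 replicates for FDR
  calibration, 1000 axes for type-I calibration) were chosen to keep the
  whole suite in the low minutes while leaving the assertions
  statistically comfortable.

## Known limitations

- The supplementary-table reproduction (published accuracies for the
  291- and 112-marker sets) runs only when those externally distributed
  tables are placed under `data/appendix/`.
- Resubstitution accuracy is an optimistic estimator by construction;
  cross-validated accuracy is implemented but not the default summary.
- The WSS-profile BIC is dimension-sensitive (see above); it is used on
  all PCs deliberately, and a different retention would change selected k.
- The segmented first breakpoint on noisy, strongly concave curves is
  sensitive to the subset grid; the default proportional grid is a
  documented modeling choice, not a universal optimum.
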