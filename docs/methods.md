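# Methods

## Correlation networks and the strong-edge statistic

All analyses operate on a genes × samples matrix of log-scale expression
(default transform log2(x+1); the log base is recorded on the container so
fold changes de-log correctly regardless of ingest base).  For every
unordered gene pair we compute Pearson's r (Spearman available as a flag:
values are rank-transformed per gene, then the same machinery applies) on
pairwise-complete observations, with the two-sided p-value from the t
approximation with n−2 degrees of freedom.  Pairs with fewer than
`min_pair_n` (default 10) joint observations keep their slot in the
network with missing r — they are never fabricated.  Genes with zero
variance over the selected samples are excluded with a report, since r is
undefined for them.

A **strong edge** passes |r| ≥ r_min and p ≤ p_max (defaults 0.5 and
0.001).  p-values are raw: the filter applies no multiple-testing
adjustment, and edge-table exports carry a note saying so.  Because p is
a monotone function of |r| at fixed n, on complete data the filter equals
the single cut |r| ≥ max(r_min, r_crit(n, p_max)); at n = 113 the
significance cut (≈0.31) is dominated by r_min = 0.5, while below n ≈ 47
significance binds.  The stratification search uses this equivalence for
fast scoring; a test asserts exact agreement with the full edge-table
route.

Correlation histograms use bins of width 0.05 spanning [−1, 1], so a bin
edge falls exactly at ±0.5 and the strong-edge cut is resolved.

## Clustering and preservation

Genes are clustered by complete-linkage agglomeration on the signed
distance d = 1 − r.  The signed form (not 1 − |r|) is deliberate:
antagonistic gene groups — positively wired within, negatively between —
are a real feature of the data and must come out as separate clusters,
which an absolute-value distance would merge.  Genes are sorted
lexicographically before clustering, making the result invariant to input
order; flat cuts are by cluster count k (default 4, exposed as a
parameter since no principled cut rule exists here) or by merge height.

Cluster preservation between cohorts is the fraction of a reference
cluster's within-cluster strong edges that remain strong in the query
network (NaN when the reference cluster has none).  Antagonism between a
designated cluster pair is reported as the mean signed r between their
genes in both networks.  Matching cluster labels across independently
clustered cohorts is done by maximal gene overlap, never assumed.

The ligand → target bipartite network keeps only strong cross-side edges;
symbols on both sides (pathway components that are themselves targets)
are excluded from the target side with a report.

## Greedy patient stratification

The hypothesis: a tumor cohort's sparse correlation network may be the
destructive superposition of subgroups with individually dense but
mutually incompatible wiring.  The search, per subgroup:

1. shuffle the cohort (seeded) and chunk into blocks of 5 (the remainder
   stays as one short block — dropping patients would break the partition
   invariant);
2. score all C(B, 5) five-block unions by strong-edge count; among the
   100 top-scoring combinations (ties broken by lexicographic block
   indices), pick the 5 most frequent blocks (ties by block index) as the
   seed group;
3. **prune**: exhaustively evaluate all pair removals, apply the best
   strictly-gaining one, repeat until no removal strictly gains;
4. **extend**: exhaustively evaluate all pair additions from the
   remaining cohort, apply the best while the score does not strictly
   decrease (zero-gain steps are accepted by default, with an optional
   consecutive-flat-step cap); the first strictly-decreasing pair is the
   cut-off and is not added.

The extension argmax is exhaustive rather than sampled; a sampled mode is
not needed at the ~120-patient scale this targets.  Every trace score is
reproducible by rescoring the recorded sample set; the whole procedure is
deterministic given matrix, cohort order and seed.

**Acceptance of a candidate subgroup** is the one place we strengthen the
procedure.  Greedy maximization overfits: on pure noise it assembles
small groups whose strong-edge count easily exceeds any fixed multiple of
the (near-zero) parental score.  We therefore run the identical
seed→prune→extend search on gene-wise sample-permuted copies of the
stage's cohort (2 runs; permutation destroys all correlation while
preserving marginals) and accept the candidate only if its score exceeds
1.5× both the parental cohort's score and the best permuted-run score.
On planted data the margin is an order of magnitude; on noise the
candidate and the bar are draws from the same distribution and the stage
is rejected.  Accepted subgroups are removed and the search repeats on
the remainder; the first rejection ends the search and the remainder is
the residual.  Iterating prune/extend to a fixed point was evaluated and
rejected: repeated pruning at small n chases the rising significance
threshold and strips genuine members.

Recovery quality varies with the seed of the block shuffle and of the
cohort itself: across development seeds the per-subgroup Jaccard against
planted truth ranged 0.65–0.97 (typically 0.8–0.95).  The weak mode is a
stage-1 seed that straddles both planted subgroups, leaving a leftover
group of genuinely correlated patients that a later stage then picks up.

## Two-cell-type heterogeneity model

Bulk samples mix cell types; if two genes are each specific to a
different cell type, variation in composition alone correlates them.  The
model: patient i has cell-type-A fraction π_i ~ Beta(mean m,
concentration c) (α = mc, β = (1−m)c; c ≪ 1 gives near-bimodal cohorts).
Per gene and cell type, the patient's cell-type expression is
N(μ, σ) on the linear scale, clipped at 0, with (μ, σ) assigned per gene
by drawing two distinct rows from a per-tissue (median, SD) panel; a
synthetic panel generator (log-normal medians, SD 20–60% of the median)
removes any download dependency.

By default the bulk log-scale value is the π-weighted mixture of the
cell-type log levels, making x exactly affine in π: in the σ → 0 limit
every composition-tracking gene pair has |r| = 1 exactly, and shifting
the mean composition at fixed var(π) provably leaves the induced
correlation structure unchanged.  A `mixing="linear"` flag instead adds
linear-scale abundances and re-logs the sum — physically motivated, but
the log curvature then makes composition artifacts depend on the mean
operating point as well (measured: ~2.2× across a 0.3–0.7 mean grid,
versus ~1.1× for log mixing).  The log-mixing default reproduces the
qualitative behavior this analysis relies on — composition *spread*, not
mean, drives fabricated correlations; both modes are available.

Sweeps hold everything but the swept parameter fixed: along the mean axis
the Beta concentration is adjusted per grid point so var(π) stays at the
base value, and simulation seeds are shared across grid points (common
random numbers).  Cell-type profiles are redrawn per simulation when a
panel (rather than a fixed profile) is supplied.

## Cohort statistics

Per gene: Kruskal–Wallis across cohorts, then Dunn's post-hoc z of each
cohort against the reference, z = (R̄_j − R̄_ref)/SE with the standard
tie-corrected variance, two-sided normal p, Bonferroni-adjusted within
the per-gene family of reference comparisons (no across-gene adjustment —
consistent with how the correlation filter also uses raw p).  There is no
dedicated Dunn package in the stack, so the statistic is implemented
directly and cross-checked against an independently coded rank-sum
oracle; under the global null its raw p rejects at the nominal rate.
Fold changes are ratios of de-logged medians.  Clinical associations use
Pearson's chi-squared without continuity correction, warning when any
expected cell is below 5.

## Synthetic cohorts

The generator is a latent-factor Gaussian model:
x_gi = baseline_g + s_g·l_g·f_{w(g),i} + ε_gi, factors f ~ N(0,1) per
sample, noise ε ~ N(0, σ²), loadings l ∈ [0,1].  The closed-form pair
correlation l_g l_h/√((l_g²+σ²)(l_h²+σ²)) makes every planted structure
checkable analytically.  Chosen over copula constructions precisely for
this tractability; it makes no attempt at count-level realism (no
negative-binomial read noise) since the analysis consumes log expression.

Ready-made specifications mirror the motivating study's scale:

* `healthy_spec` — 113 samples, 4 clusters × 24 genes, clusters #1 and #4
  sharing a factor with opposite signs (the antagonistic pair), default
  loading 0.8 and noise SD 1.0 (planted r ≈ 0.39: visible to clustering
  but below the strong-edge cut, as in a weakly coherent tissue); for
  analyses that need a coherent reference network, noise SD 0.5 (r ≈
  0.72) is used.  Optional target genes load the antagonistic factor with
  alternating sign.
* `tumor_spec` — 118 samples: subgroup A (40) with the base wiring;
  subgroup B (40) *rewired* — its own pool of 8 fresh factors, each gene
  reassigned with a random sign, so B's strong pairs coincide with A's
  only at random-overlap rates and the coincident half cancels under
  superposition; and 38 decorrelated patients, each gene given a private
  factor so their variance matches the structured strata (a lower-variance
  noise stratum would let the greedy search exploit them as cheap
  sample-size padding).  Per-gene loadings are graded 0.55–0.95 so planted
  correlations span a band around the 0.5 cut and greedy steps see a real
  gradient — a single planted r value produces degenerate flat plateaus.
* `noise_spec` — pure i.i.d. noise (loading 0) for null calibration.

`cancerize` regenerates the factor contribution of every gene outside a
retained cluster set as an independent per-gene draw of the same
amplitude, keeping the original noise term: within-cluster correlation
collapses to the null level while every marginal mean and variance is
preserved.

## Problem sizes and numerical choices

Analyses and tests run at the study's own scale — ~100 genes, 113–118
samples, 40 clustering seeds, 500 subsamples, 50–100 mixture simulations
per sweep point — which keeps the full pipeline within minutes on one
CPU.  Ties everywhere break lexicographically (gene symbols, sample ids,
block indices), making every stage deterministic under a fixed seed.
Boundary semantics are inclusive: r = 0.5 with p = 0.001 is a strong
edge.  Matrix round-trips write floats with %.17g and parse with exact
float conversion, so write→read reproduces values bit-identically.

## Limitations

The Gaussian generator validates the *machinery*, not the biology: it
contains no count noise, no batch effects, no outlier samples, and its
planted subgroups are cleaner than real tumor strata, so passing tests
bound algorithmic correctness rather than clinical performance.  The
greedy stratification is a heuristic with seed-dependent recovery (see
above) and no global optimality guarantee — deliberately so, since the
procedure itself is the object under study.  Strong-edge p-values are
raw by design; users needing family-wise control should treat the edge
lists as exploratory.
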