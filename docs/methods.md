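# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Spatial quantitative immunofluorescence

**Surface.** The "in-silico embryo surface" is the boundary of the 3-D
Delaunay complex of all nuclear centroids of one embryo, i.e. their convex
hull. Blastocysts are approximately convex, and for a convex cloud the
Delaunay boundary and the hull coincide; non-convex (alpha-shape) surfaces
are out of scope. qhull is run with triangulated output (`Qt`), so the
surface is a closed triangle mesh with F = 2V − 4; every returned surface
is audited for watertightness in the tests. Coplanar or collinear
centroids raise an explicit degenerate-geometry error naming the embryo.

**Features.** The distance from each centroid to each triangle uses the
standard barycentric region decomposition (face / three edges / three
vertices). Per nucleus we keep the minimum over all faces and the
population variance over all faces. Both features are invariant to rigid
motions (audited to 1e-9).

**Classifier.** 2-means on the standardized feature pair. The published
procedure specifies neither initialization nor scaling; we standardize
both features to unit variance (their raw scales differ by orders of
magnitude: µm vs µm²) and use a deterministic greedy farthest-point
initialization — center one is the point farthest from the data mean,
center two the point farthest from center one — followed by Lloyd
iteration. This initialization is deterministic and invariant to row
order, so random restarts add nothing and a single run suffices; the
`seed` argument is recorded for provenance only. The cluster with larger
mean minimum distance is "inside" (ties: smaller mean variance).

**Kruskal–Wallis.** H uses midrank tie correction; p comes from the χ²
approximation (df = groups − 1). For total n ≤ 10 an exact permutation p
(full enumeration of group assignments) is available. The χ² approximation
is known to be rough at such sizes: on continuous data with total n = 8 it
differs from the exact tail by ~0.1 in the mid-range of p, a property of
the approximation itself (the exact enumeration here is verified against
an independent brute-force oracle). Use the exact option whenever n
permits.

**Intensity normalization.** The published figures do not state their QIF
normalization. Two conventions are provided and recorded in the output
metadata: (default) log-transform then per-embryo z-score, and division by
the per-embryo median of a reference channel (e.g. DAPI). Neither is
asserted to be the original authors' choice.

## Expression core

FPKM matrices are genes × cells with strict validation (no duplicates,
finite nonnegative values). The expressed-gene filter keeps genes with
FPKM > 0 in at least one condition. Log transformation is log₂(FPKM + 1);
the pseudocount (unstated in the source analyses) is configurable.

**HVG selection.** Per gene: mean of log₂(FPKM+1) across cells, and CV² =
var/mean² of raw FPKM (matching the phrase "square of coefficient of
variation"); logCV² is log₁₀ of that value (base configurable). A lowess
curve of logCV² on mean (span 0.3) plays the "nonlinear regression"
trend. Default selection requires mean > 0.5, logCV² > 0.5 *and* a
positive residual above the trend; a thresholds-only switch reproduces the
bare two-threshold rule, since the published wording supports either
reading. Selection is deterministic and invariant to relabeling.

## Coexpression

Unsigned adjacency |cor|^β with β = 10; TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i,k_j) + 1 − a_ij); modules from average-linkage clustering of
1 − TOM with a *static* cut at 0.35 and minimum size 30. A static cut is
the minimal faithful reading of a single stated distance; dynamic tree cut
is out of scope. Module ids order by decreasing size. Eigengenes are the
first right singular vector of the z-scored module submatrix, scaled to
unit (population) variance and oriented to correlate positively with the
module's mean standardized profile — making results bit-reproducible.
"ward.D2" in `hierarchical_cluster` is the squared-Euclidean Ward update
(scipy's `ward` on raw observations).

## Trajectory

Diffusion maps: Gaussian kernel on Euclidean distances with a *global*
bandwidth (median pairwise distance by default; the commonly used library
applies local sigmas — the global variant is this package's declared,
configurable choice), optional density normalization K ← K/(qqᵀ), row
normalization to a Markov matrix, spectrum via the symmetric conjugate,
and embedding coordinates λ_i ψ_i for eigenpairs 2..(k+1). Signs follow a
largest-magnitude-entry convention. Pseudotime is the Euclidean (diffusion)
distance from an explicit root in that space, min–max scaled to [0,1]; the
root is a required user choice (the original pseudotime construction and
root are unstated, so figure axes can only be matched qualitatively).

Trajectory lines are cubic smoothing splines (second-derivative roughness
penalty, weight λ = 0.01) per embedding coordinate against pseudotime;
duplicate abscissae are averaged and at least 5 distinct abscissae are
required (the natural-spline constructor's minimum). The λ → ∞ limit
approaches the least-squares line; numerically the banded solver is clean
up to λ ≈ 1e4–1e6 and degrades beyond, so the limit is audited in that
range. Gene trends use locally weighted quadratic regression with tricube
weights (span 0.5 of the data per window; windows with fewer than 3 points
raise an error advising a larger span) — written here because the
available lowess implementation is degree-1 only.

## Deconvolution ("fraction of identity")

Mixing is modeled linearly in FPKM: x ≈ S f with f on the probability
simplex. Genes used are those with FPKM above a threshold (default 0) in
the query *and* every signature column — the conservative reading of
"overlapping expression (FPKM > 0)"; a flag relaxes to query-only, and the
threshold exposes the alternative log₂FPKM > 0 (FPKM > 1) filter. The QP
is solved as NNLS on the system augmented with a sum-to-one row of weight
1e6 (rows pre-scaled by the largest signature entry), then renormalized;
the solution is checked in the tests against a dense simplex grid search
and always returns a feasible simplex point, even for rank-deficient
signatures (flagged, with a warning). Group summaries report per-group
medians and Welch t-tests (identical degenerate groups return t = 0,
p = 1 by convention).

## Set statistics

Differential expression is a two-sided Wilcoxon rank-sum test on
log₂(FPKM+1) per gene — a deliberate, documented stand-in for error-model
based single-cell DE (dropout error models are not re-implemented, so
published per-gene adjusted p-values are not numerical targets). Exact
null for combined n ≤ 12 without ties, tie-corrected normal approximation
otherwise; effects are differences of group means of log₂(FPKM+1);
Benjamini–Hochberg adjustment across tested genes. Markers are genes with
adjusted p < 0.05 and the requested effect sign.

Ternary fractions divide each gene's three group means by their sum
(zero-total genes dropped and reported). The density-bias test partitions
the simplex into three apex regions (max fraction > 0.6 — a declared
convention; the original work only plots densities), three edge regions
(smallest fraction < 0.15) and a center, and permutes cell group labels
for a one-sided count null, BH-adjusted across regions.

The pathway statistic uses r_g = 100·mean_A/(mean_A+mean_B) per pathway
gene; the cumulative-sum curve of sorted r_g is reported and the scalar
test statistic is Σ(r_g − 50), with a two-sided cell-label permutation
null. The exact published construction is unstated; this formalization is
one defensible reduction and is exposed alongside the raw curve.

Hypergeometric enrichment is one-sided (over-representation), with sets
intersected with an explicitly supplied universe (which universe the
original analysis used is unstated, so it is a required input). Preranked
GSEA uses the classic running sum (hits +1/k unweighted or |score|-
normalized at weight 1, misses −1/(N−k)), ES = maximum-magnitude
deviation, a uniform gene-label permutation null, NES = ES over the mean
same-sign |null ES|, and a same-sign tail p. All permutation p-values are
of the form (1 + exceedances)/(1 + draws), hence in
[1/(n_perm+1), 1], and are seed-reproducible.

## Synthetic data

The generators are pure functions of their parameters including the seed;
independent sub-streams per purpose keep e.g. outer-shell draws unchanged
when inner nuclei are added.

**Embryos.** Outer (TE) nuclei on a radially jittered ellipsoidal shell
(default sphere, radius 30 µm, jitter sd 1 µm, 60 nuclei); inner (ICM)
nuclei as a Gaussian clump (sd 6 µm = 0.2·radius, 15 nuclei) displaced
0.45·radius toward one pole and rejection-sampled inside a safety radius
so the clump stays strictly interior — these defaults describe a mid
blastocyst (~75 cells, ICM at one pole). Channel log-intensities are
normal per lineage (lognormal intensities), volumes lognormal around
600 µm³. Not emulated: nuclear shape, segmentation errors, imaging
attenuation with depth, mural/polar TE substructure — so a perfect score
here shows the geometry/classification chain is correct, not that real
embryos classify this cleanly.

**Expression.** log₂ mean = baseline U(1,6) + class-signature effect
(+2 log₂ units for 25 genes per class by default) + module program +
trend; FPKM = 2^(mean + ε) with ε ~ N(0, 1) (lognormal noise of one
log₂-unit sd, giving background CV² ≈ 0.6, in the range of real
single-cell FPKM data). Planted HVGs multiply the noise sd by 4. Module
programs are two-state: half the cells are "on" and module genes gain
2 × 6 log₂ units times a U(0.9, 1.0) loading. The one-sided, binary
design is deliberate: lineage programs are approximately on/off, and a
binary program survives the FPKM floor and the log₂(x+1) compression
undistorted, whereas a wide symmetric Gaussian factor would spend a third
of its mass below the floor. Trend genes change linearly in log₂ space by
±4 units across a latent cell order. All planted sets are disjoint. Not
emulated: dropout as a separate zero-inflation process, library-size
variation, batch effects, correlated backgrounds — recovery scores on
these simulations are upper bounds on real-data behavior.

**Mixtures.** Query profiles are exact signature combinations with
optional multiplicative lognormal noise; fractions are recorded as ground
truth.

## Problem sizes

The test suite and acceptance script run, per stage: 50 embryos of 75
nuclei (classification), 1,000 random point–triangle cases against the
sampling oracle, 60 exact Kruskal–Wallis fixtures (n = 8), ten 2,000-gene
HVG simulations, ten 400-gene/4-module recoveries, 100 three-class
mixtures (noiseless and sd-0.1), ten 60-cell pseudotime trajectories, one
2,000-gene DE simulation, and exhaustive enumerations over 15-gene
universes. These sizes make every check rerunnable on a laptop core in
well under a minute per stage.

## Known limitations

- The χ² Kruskal–Wallis p is inaccurate at n ≤ 8 (see above); the exact
  option exists for exactly this reason.
- Diffusion pseudotime assumes a single unbranched trajectory; no
  branching assignment is provided.
- The static module cut at 0.35 is sensitive to the overall correlation
  level of the input; it is the stated constant, not an adaptive choice.
- Deconvolution assumes linear mixing of FPKM and a full-column-rank
  signature on the overlapping gene set; rank deficiency yields a flagged
  minimum-norm solution.
- The DE stand-in ranks genes well but its p-values are not those of an
  error-model method; treat them as ordering devices on real data.
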