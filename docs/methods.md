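# Methods

## Problem and model

Quality control of high-dimensional molecular data (expression matrices with
d features ≫ n samples) needs an *objective* rule for flagging outlier
samples, applicable separately to each experimental group while all groups
are displayed in one shared low-dimensional space. `depthqc` implements the
depth-based generalization of the boxplot for this purpose: the **bagplot**
in two dimensions and the **gemplot** in three and four, computed on
principal-component scores.

The pipeline is:

1. **PCA on all samples jointly.** The n × d matrix X is column-centered and
   decomposed via its thin SVD, which is the n-dominant dual route to the
   eigendecomposition of the sample covariance S. Scores Z = X_c·A, where the
   columns of A are the eigenvectors of S; λ_j equals the variance of score
   column j and V_j = λ_j / Σλ_j is reported as the scree sequence. No
   per-group PCA is ever performed: groups must be comparable in one space.
   Centering yes, unit-variance scaling no (covariance PCA); a `scale` flag
   exists but is off by default. Loading signs are fixed (largest-magnitude
   entry positive) for cross-platform reproducibility.

2. **Per-group depth geometry.** For each group, in the subspace of the
   first 2 (bagplot) or 3–4 (gemplot) components:

   - The **halfspace location depth** of a location θ is the smallest number
     of group observations in any closed halfspace whose boundary passes
     through θ. Closed counting: a point on the boundary hyperplane counts on
     both sides (relative tolerance 1e-9).
   - The **depth region** D_k is the set of all θ with depth ≥ k; the
     **depth median** T is the deepest location (center of gravity of the
     maximizing grid nodes when tied; their hull is retained as an innermost
     gem).
   - The **bag** interpolates between D_{k*} and D_{k*−1}, where k* is the
     level with #D_{k*} ≤ ⌊n/2⌋ < #D_{k*−1}, using the weight
     λ = (⌊n/2⌋ − #D_{k*}) / (#D_{k*−1} − #D_{k*}), so the bag holds about
     half the observations — the multivariate box.
   - The **fence** inflates every bag vertex by a factor (default 3)
     relative to T; the **loop** is the hull of the observations inside the
     fence. Observations strictly outside the fence are the outliers
     (boundary points, within tolerance, are not flagged). The loop is
     *defined by* the within-fence points, so fence membership is the
     flagging primitive; the two rules coincide by construction.

3. **Union protocols.** The `1D` method applies the boxplot 1.5 IQR rule
   (linear-interpolation quartiles) to each of the first three score columns
   per group and flags the union; `2D` applies the bagplot to every
   unordered pair of the first three components and flags the union; `3D`
   and `4D` run one gemplot in the leading subspace. Every flag records its
   provenance (which component, pair or subspace triggered it).

## Depth computation

Two independent routes are implemented and tested against each other:

- **Sweep route (production).** For a query θ, every data direction
  v_i = x_i − θ defines a circle of halfspace normals orthogonal to it. On
  that circle the closed-halfspace count is a sum of half-circle indicator
  intervals, so its minimum over the open arcs of the induced arrangement is
  found by an event sweep in O(n log n); correcting the on-circle count by
  the parallel/antiparallel multiplicities yields the counts of the cells of
  the full normal arrangement adjacent to the circle. Every cell of the
  arrangement touches some circle, so the minimum over circles is the exact
  depth: O(n² log n) per query in 3D. In 4D the same reduction is applied
  recursively over 2-sphere sub-arrangements. The kernels are numba-compiled
  and use a bucketed counting sort over trigonometry-free pseudo-angles.

- **Brute-force oracle.** Candidate boundary orientations induced by single
  points (2D: critical angles ± π/2, evaluated at criticals and at arc
  midpoints) or point pairs (3D: cross products with ± ε perturbations along
  the two defining directions, plus an affine-rank reduction for degenerate
  configurations). Exact for data in general position; used for small exact
  queries and as the independent test oracle.

The **depth grid** lays a regular lattice over the bounding box of the
group's scores, extended by 10% of the per-axis span, with 30 nodes per axis
in 2D/3D and 15 in 4D, and stores the exact depth at every node. Nodes
outside the convex hull of the points have depth 0 and are short-circuited
via a Delaunay point-location test. Defaults: the source method leaves the
resolution unspecified; 30 nodes/axis makes the discretization error of the
median location about 1.5% of the data span per axis while keeping a 3D grid
of 100 points near one second. Resolution, padding and fence factor are
exposed everywhere. Rank-deficient clouds (e.g. collinear scores) are
detected by an SVD rank check; the grid is then built inside the affine span
with a warning, and flags are decided in that span.

## Region geometry: counts from points, hulls from points, median from the grid

A subtlety matters at practical resolutions. The member counts #D_k that
drive k* and λ are computed *exactly* from the per-observation depths: an
observation belongs to D_k iff its own depth is ≥ k. Counting instead via
hulls of lattice nodes (an inscribed approximation of D_k) undercounts by
the one-spacing boundary shell — which at resolution 30 spans several depth
levels — biasing k* down; in the worst case the outer interpolation region
degenerates to the data hull and a gross outlier drags the bag toward
itself, silently disabling detection.

For the interpolation geometry, the regions are realized as convex hulls of
the observations with depth ≥ k. Halfspace depth is quasi-concave, so this
hull contains exactly the #D_k member points and is a faithful inner
approximation of the true region. The bag is then the star-shaped blend
anchored at T: along every ray from T to a vertex of either region, the bag
boundary sits at (1 − λ)·(exit of D_{k*}) + λ·(exit of D_{k*−1}); using both
vertex sets guarantees bag ⊇ D_{k*}-hull. Because the blended hull's member
count is not linear in λ, λ is not taken from the closed-form count ratio
but calibrated by bisection to the weight whose bag membership is closest
to ⌊n/2⌋ (preferring inclusion on ties) — the count ratio is the bisection's
conceptual target, the membership the bag actually achieves is what is
controlled. Fence inflation acts on bag vertices, which is exact for convex
polytopes. The lattice remains the source of the depth median and of the
rendered gems.

Measured on bivariate standard-normal samples of 100 points (20 seeds), the
calibrated bag holds 48–53 observations (mean ≈ 50.5); the residual spread
reflects the discreteness of hull membership as the blend weight varies.

## Cluster baseline

Single-linkage hierarchical clustering (Euclidean distance by default) with
an objective read-out: each sample's **first-merge height** — the height at
which its singleton first joins any cluster — is its outlyingness score, and
the boxplot rule applied to these heights flags samples above the *upper*
fence only (low heights mean tight clustering). The per-observation
first-merge statistic is the default; computing the fence from all n − 1
merge heights is exposed as an option. Trees are built per experimental
group. Newick export is provided for external tree viewers.

## Synthetic data

The generators reproduce the study conditions the method was evaluated
under; their defaults are those conditions.

- **Artificial components, example 1:** two groups of n = 100 i.i.d. 3D
  points from N(−3, 1) and N(+3, 1) per coordinate; observation 3 of group 1
  overwritten to (−6,−6,−6) and observation 8 of group 2 to (6,6,6) — each
  planted point 3σ outward of its group center per coordinate.
- **Artificial components, example 2:** group 1 draws z2 from Exp(λ = 4) and
  z1, z3 from N(3, 1); group 2 draws z1, z3 from the exponential and z2 from
  N(3, 1). Observations 73 and 87 of group 1 are overwritten to (3, 4, 25)
  and (3, 10, 4). The Exp(λ = 4) notation is read as *mean 4* (scale
  convention): that is the only reading under which the planted coordinates
  behave as described — unremarkable in their non-extreme components (3 and
  4 sit in the bulk of N(3,1) and Exp(mean 4)) while 25 is a 22σ excursion
  of z3. Under the rate-4 reading (mean 0.25) a planted z2 of 4 would be 16
  mean-units out and the PC1×PC2 bagplot would flag it, contradicting the
  documented behavior. `exp_convention="rate"` selects the other reading.
- **Expression simulation:** X ~ N_d(group mean, Σ) with d = 1000 genes,
  n = 100 samples per group and an autoregressive covariance
  σ_ij = ρ^(τ·|i−j|) (ρ = 0.75, unit diagonal); larger τ means faster decay,
  i.e. *less* correlation. Setting 1 is one group (mean 0); setting 2 adds a
  second group at constant level κ = 5. Three outlier samples per group are
  drawn from means offset by a fold-change fc in sign blocks of width d, d/2
  and d/4, so each planted outlier projects onto a different leading
  component direction. Outlier rows are appended after the regular rows with
  deterministic identifiers; one Cholesky factor of Σ is shared across the
  replicates of a scenario.

What the generators do *not* emulate: count-data distributions (negative
binomial), library-size or batch effects, within-group correlation of
scores, or real annotation. Passing tests therefore demonstrate the
geometry and the protocol, not robustness to RNA-seq technical artifacts;
real count matrices should be variance-stabilized (e.g. `log2(x+1)`, exposed
as `--transform log2p1`) before PCA.

## Benchmark harness

`run_benchmark` replicates simulate → PCA → detect over a scenario grid and
reports mean sensitivity (flagged ∩ planted / planted) and specificity
(1 − false flags / regular) with Monte-Carlo standard errors; replicate r of
scenario s uses an independent generator seeded by (seed, s, r), so the
whole table is reproducible from one integer. The packaged checks run 100
replicates per scenario at d = 1000 (the original study used 1000
replicates) with fc = 1, the smallest fold change of the simulated sweep
(fc = 1…4) and the condition with the largest non-saturated sensitivity
contrasts; at this scale the qualitative pattern — boxplot most sensitive,
gemplot most specific, all methods more sensitive under weak gene-gene
correlation — is stable, and it reproduces across the whole fc sweep. A
d = 200 reduction was evaluated and rejected: at τ = 0.01 the correlation
length of Σ (~350 genes) exceeds 200, which distorts the covariance
structure enough to invert the τ ordering.

One caveat on comparing the boxplot and bagplot protocols: in this
implementation their sensitivities, specificities and per-replicate flag
counts all differ by less than the Monte-Carlo error at the smallest fold
changes, with seed-dependent sign — the pairwise bagplot catches planted
shifts that split across two components and that no single coordinate
resolves, which lifts it to the boxplot's level. No ordering between 1D
and 2D is therefore asserted. The gemplot's position is unambiguous: it
flags the fewest samples, has the lowest sensitivity and the highest
specificity of the three at every condition examined.

## Numerical choices and degenerate inputs

- Boundary conventions: closed halfspaces in depth; region membership
  boundary-inclusive; outlier = strictly outside the fence; all with
  relative tolerance 1e-9.
- Ties in the depth median: center of gravity of all maximizing nodes, hull
  retained.
- #D_{k*−1} = #D_{k*} ⇒ λ = 0; no level ≤ ⌊n/2⌋ ⇒ fall back to the deepest
  level with a warning.
- Groups smaller than 10 are refused by the bag constructor (the k* rule is
  unstable there) and skipped with a warning by the 2D/3D protocols; the 1D
  method needs only 4 observations.
- Constant matrices, non-finite values, duplicate identifiers and unlabeled
  samples are rejected with specific errors.
- 4D gemplots are supported but O(n³ log n) per grid node; they are intended
  for small grids (resolution 15) and moderate n.

## Known limitations

- Depth is computed exactly at lattice nodes, but the depth *median* is
  still a lattice quantity: its location is discretized to the grid, and
  with it the fence anchor. Finer grids tighten this at cubic cost in 3D.
- The bag's member count is exact only up to the discreteness of consecutive
  depth levels; the constructed bag holds ⌊n/2⌋ within about ±2 points for
  n = 100.
- p > 4 is out of scope, as are robust/sparse PCA variants; with heavy
  within-group score correlation, the shared PC space may not represent a
  group's principal directions (a caveat inherent to the joint-PCA design —
  inspect the scree values attached to every report).
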