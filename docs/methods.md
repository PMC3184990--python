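# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions a
user re-implementing or auditing the package needs.

## Superimposition

Configurations of k 2D landmarks are centered, scaled to unit centroid
size, and iteratively rotated to the running consensus by least
squares (proper rotations only; leaves are digitized on one side
consistently, so reflections are never admissible). Convergence is
declared when the summed squared change of the consensus falls below
1e-10 — far below any printed precision — with a 100-iteration cap;
non-convergence is flagged on the result rather than raised.

The fit is a **partial** Procrustes fit: specimens keep unit centroid
size and no cosine rescaling is applied. A full fit (per-specimen
rescaling by cos ρ) is available via `fit="full"`; for the small shape
variation this pipeline targets the two differ below the third
decimal. After convergence the consensus is rotated onto its principal
axes, and the 180° ambiguity is resolved by making its first nonzero
coordinate positive — a rotation, never a reflection — so repeated
runs produce identical coordinates.

Shapes are then projected **orthogonally** onto the tangent plane at
the consensus. Two consequences worth knowing: the tangent distance of
a specimen to the consensus equals sin ρ of its Riemannian distance ρ,
so the tangent-check regression slope can never exceed 1; and each
projected deviation is exactly orthogonal to the four similarity
directions (two translations, scaling, rotation) at the consensus,
which is what makes the partial-warp + uniform score decomposition
distance-preserving to machine precision.

The tangent check regresses, through the origin, tangent Euclidean
distances on ρ = arccos⟨x, c⟩ and reports slope and uncentered
correlation; values ≈ 1 justify treating the coordinates as ordinary
Euclidean variables downstream. The Bookstein two-point registration
(`baseline_superimpose`) is included for the demonstration that shape
*distances* are essentially superimposition-independent even though
per-landmark displacement pictures are not.

## Hierarchical ANOVA

Variation in size (univariate) or shape (2k coordinates) is
decomposed by sequential nested group means: populations about the
grand mean, trees about their population means, leaves about their
tree means, observations about their leaf means. For a purely nested
design this equals the type-I SS of the corresponding indicator
regression, balanced or not (the test suite asserts this against a
brute-force regression oracle). Shape uses the isotropic model: the
shape SS of a stratum is the plain sum of its coordinate-wise SS.
This buys a simple F table at the cost of assuming equal,
direction-free variation at every landmark; when that assumption is
badly violated the P values are only indicative.

F ratios follow the random-effects logic of the design:
populations/trees, trees/leaves, leaves/error. P values come from the
F distribution at the chosen df convention:

* `morphoj` (default): populations P−1, trees T−1,
  leaves (L−1)−(P−1)−(T−1), error n−L; shape dfs multiply by 2k−4.
  For the 2×22×2×2 design this gives 1/43/43/88 (and ×18 for shape).
  This convention double-counts one df between populations and trees
  but reproduces the tables produced by the software lineage this
  protocol standardizes.
* `nested`: the orthodox counts T−P and L−T (42/44). Offered because
  the default's bookkeeping is defensible only as compatibility.

Percent SS is 100·SS(effect)/SS(total); it describes fit, not variance
components (no REML/method-of-moments estimation is attempted).

## Tree averaging and the two-group battery

Multiple leaves of one tree are pseudoreplicates; all population-level
tests therefore run on tree means of the aligned coordinates and of
centroid size. Multivariate statistics (Hotelling T², Mahalanobis
distance, discriminant analysis, Box's M, MANCOVA) operate on the
principal-component subspace with eigenvalues above 1e-12 of the
largest, i.e. on the true 2k−4 shape dimensions, so dfs are correct.
Permutation tests use B = 10000 label permutations by default,
two-sided via the absolute statistic, with
P = (1 + #{permuted ≥ observed})/(B + 1); the Mahalanobis variant
re-estimates the pooled covariance under every permutation. All
permutation seeds are explicit arguments.

The discriminant rule is the two-group linear one —
w = S⁻¹(m₁ − m₂), classification by smaller Mahalanobis distance,
equal priors (the design is balanced; priors are configurable), ties
to the first group with a warning. Jackknife cross-validation refits
means, pooled covariance and the rule with each specimen held out.
Resubstitution tables are reported only to exhibit their optimism.

## Allometry and size-correction

Allometry is the multivariate regression of shape on centroid size
(optionally log size; for a ~3 % size range the two are
indistinguishable, which a test asserts). The MANCOVA tests, on the
PC subspace of dimension p with n tree means:

| term | full model | reduced model | df2 |
|---|---|---|---|
| slopes | 1 + group + size + group·size | drop interaction | n − 4 − p + 1 |
| intercepts | 1 + group + size | drop group | n − 3 − p + 1 |
| size only | 1 + size | drop size | n − 2 − p + 1 |

Each term has one hypothesis df (two groups, one covariate), so
Pillai's trace V converts exactly to F = (V/(1−V))·(df2/p) on
(p, df2). The `pct_explained` column is the incremental fit — the drop
in residual SS when the term enters, as a percent of total shape SS.
An alternative definition (total fit of the full model per term) can
be read off the same table by cumulating rows; the package commits to
the incremental one because it decomposes additively.

Size-correction estimates the common within-group slope B by pooled
regression of within-group-centered shapes on within-group-centered
sizes, then replaces each shape by shapeᵢ − B(sizeᵢ − s₀). The common
size s₀ defaults to the grand mean; because the fitted lines are
parallel, group mean differences of the corrected shapes are invariant
to s₀ (asserted to 1e-10). The function refuses to run when the
caller supplies a slopes-test P < 0.05 unless `force=True`, since
parallelism is the correction's premise; the large-sample exception
(significant but practically negligible slope differences) is exactly
what the override flag is for.

## Thin-plate splines and diagrams

The TPS kernel is U(r) = r² log r² with U(0) = 0 (the r² log r
convention differs only by a factor 2 absorbed into the weights). The
standard L-system is solved per output coordinate; a rank check on the
affine block rejects collinear references before the solve. Bending
energy is trace(WᵀKW), zero exactly for affine targets. Jacobian
expansion factors use the analytic derivative
∂U/∂x = 2(x−xᵢ)(1 + log r²); negative determinants (fold-over, normal
at large magnification) are returned as-is with a warning rather than
raised. Grids default to 20×20 cells over the reference bounding box
expanded by 10 % — the figures this mimics never state their density,
so these are package choices. Magnification is the affine map
reference + m·(target − reference); diagrams carry m explicitly.

Principal warps are eigenvectors of the bending-energy matrix (the
upper-left k×k block of L⁻¹), with k−3 nonzero eigenvalues; the
uniform components are computed numerically as the orthonormal
complement of the partial-warp subspace within the tangent space,
avoiding commitment to any closed-form uniform parameterization. The
combined scores reproduce tangent distances to 1e-9, which the
acceptance suite asserts.

## Synthetic data

The generator emulates the study design this protocol was built
around: 2 populations × 22 trees × 2 leaves × 2 replicas of an
11-landmark half leaf. Effects are drawn in the orthonormal basis of
the 2k−4 tangent space at a fixed template (so nominal SDs are exact
per shape dimension) and added: a fixed ± population offset, isotropic
tree and leaf effects, replica digitizing noise, and an allometric
term a·(size − mean size) with one shared direction a. Sizes are
lognormal around population means with tree, leaf and replica factors,
keeping them positive and mildly right-skewed. Labels follow the
`Campo_T01_L1_R1` convention (population chars 1–5, tree 1–9, leaf
1–12, replica 15) and round-trip through the classifier parser.

Defaults are calibrated so the closed-form expected stratum shares
(`expected_stratum_shares`) reproduce the study conditions: for shape
≈ 3 / 62 / 34 / 0.1 % (populations/trees/leaves/error) with mean
specimen-to-consensus distance ≈ 0.11; for size ≈ 6 / 55 / 39 /
< 0.1 % around a 70 mm mean with a 1 mm population gap; allometry
explains a few percent of tree-level shape variance. Note the
calibration implies a per-coordinate *leaf* SD (0.0225) above the
*tree* SD (0.0154): stratum shares accumulate the means of everything
nested below, which is why the tree stratum still dominates — the same
arithmetic operates in the real ANOVA.

What the generator does **not** emulate: anisotropic, spatially
correlated landmark variation (real leaf variation concentrates in a
few directions, so a real PCA front-loads variance far more than the
isotropic synthetic one); measurement error correlated between
landmarks; unbalanced sampling; and any biomechanics of leaf growth.
Passing tests on this generator therefore validate the estimators'
arithmetic and calibration under the stated model, not the biological
realism of any particular dataset.

Null scenarios (`no_group_difference`, `no_allometry`, `equal_slopes`)
zero one effect each and drive the type-I calibration suites, which
check Hotelling, the MANCOVA slopes term and the permutation tests
against binomial 99 % bands at α = 0.05 over 200 replicates. The
null-data discriminant check uses a replicate-level band for the
jackknife accuracy because leave-one-out predictions within one
dataset are mutually dependent; pooling them as independent Bernoulli
trials understates their variance by roughly a quarter.

## Problem sizes and determinism

The test suite and the acceptance script run the full design (176
observations), 50-seed parameter recovery, and 200-replicate
calibrations; these sizes were chosen because every Monte-Carlo band
stabilizes well below them while the whole suite stays in the
seconds-to-minutes range on one core. Every stochastic routine takes
an explicit seed; identical seeds give byte-identical outputs,
including the permutation P values and the acceptance JSON.

## Known limitations

* 2D only; no object symmetry handling, no semilandmarks or outlines
  as analysis variables (outlines are visualization-only).
* The isotropic shape ANOVA and the `morphoj` df convention are
  compatibility choices, not statistical recommendations; the nested
  convention and the PC-subspace multivariate tests are the defensible
  alternatives the package also provides.
* Variance components (as opposed to percent SS) are not estimated.
* The two-group discriminant path does not generalize to ≥3-group CVA
  ordination; typicality probabilities are not computed.
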