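# Methods

This note documents the models and procedures implemented in `phylomorph`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Superimposition

**Generalized Procrustes analysis.** Configurations of K 3D landmarks are
centered, optionally scaled to unit centroid size (full Procrustes, the
default), and iteratively rotated onto a consensus.  Each rotation is the
proper-rotation (determinant +1) optimum from the SVD of the
cross-covariance matrix, so reflections are never introduced.  The
iteration reference is the mean shape rescaled to unit centroid size;
convergence is declared when the squared change of the consensus falls
below 1e-24 (at most 1000 iterations), which stabilizes the consensus to
~1e-12 and makes the alignment invariant to input ordering and to
similarity transforms of the inputs at ~1e-9.  The *reported* consensus is
the plain arithmetic mean of the aligned shapes.

**Object symmetry.** For bilaterally symmetric structures the 2n-set of
originals plus reflected, relabeled copies (reflection = negation of the
first coordinate axis; the choice of plane is immaterial because GPA
removes orientation, and it is fixed for reproducibility) is superimposed
jointly.  The symmetric component of a specimen is the mean of its two
aligned copies and the asymmetric component half their difference, so the
decomposition reconstructs the aligned original exactly (to 1e-12).  All
downstream statistics consume the symmetric component.

**Missing landmarks.** Estimated before superimposition with a 3D
thin-plate spline, kernel U(r) = r plus an affine polynomial part, fit from
a reference's landmarks at the specimen's present positions.  Because the
affine part reproduces any affine map exactly, the reference's coordinate
frame is irrelevant.  The reference is the GPA consensus of the complete
specimens of the same species when at least three exist, otherwise the
global consensus.  The linear system is solved directly; numerically
singular systems (fewer than four common landmarks, or coplanar ones) are
rejected rather than regularized.

**Tangent space.** Analyses use the Procrustes coordinates directly; the
PCA of the coordinate covariance serves as the tangent-space
approximation.  Components with numerically zero variance (the
superimposition constraints remove 7 of the 3K dimensions) are dropped, so
percent-variance sums to 100 and full-space score distances equal
Procrustes distances.

## Linear models and permutation inference

Shape ANOVA fits ordinary least squares on the flattened coordinates with
sequential (Type I) sums of squares.  Significance uses residual
randomization (RRPP): for each term, the residuals of the reduced model
(all preceding terms) are permuted across specimens, added back to the
reduced-model fitted values, and the statistic recomputed; the observed
value is included in the permutation distribution and in the p-value
denominator, so p ∈ (0, 1].  The effect size Z is the standard deviate of
the observed statistic within its permutation distribution, computed on
log F by default (raw F when any permuted F is non-positive); both
behaviours are available behind the `effect_size_on_log` flag because
published Z values differ between the two conventions.

The minimal-p example (a group shift far above noise giving
p = 1/(n_perm+1)) holds only when permutations that preserve the grouping
are vanishingly rare; with two groups of 10 that probability is about
1e-5, which is the regime the tests use.

**Phylogenetic ANOVA.** Data and design — including the intercept — are
premultiplied by T = C^{−1/2} (eigendecomposition of the Brownian-motion
covariance C; eigenvalues at or below 1e-12 of the largest raise a tree
error rather than being pseudo-inverted), after which the identical
sequential-SS / RRPP engine runs.  With C = I the transform is exactly the
identity, so the phylogenetic ANOVA reproduces the ordinary one bit for
bit under the same seed — a property the tests assert.

**Disparity.** Overall disparity is the Procrustes variance
MD = Σᵢ d²(xᵢ, grand mean)/(N−1).  A group's partial disparity restricts
the numerator sum to its members while keeping the grand-mean residuals
and the N−1 denominator, so ΣPD = MD holds as an identity (asserted at
1e-12).  The per-group variance about the group's own mean divides by n_g
by default (Procrustes-variance convention); an `group_variance_ddof=1`
switch gives the n_g−1 version, since published tables cannot adjudicate
between them without raw data.

## Phylogenetic signal

The multivariate K statistic is the ratio of observed to
Brownian-motion-expected trait variance: with the phylogenetically
weighted mean a = (1′C⁻¹1)⁻¹1′C⁻¹Y and r = Y − 1a,

    K = [ tr(r′r) / tr(r′C⁻¹r) ] / [ (tr C − n/(1′C⁻¹1)) / (n−1) ].

K = 1 under Brownian motion for any tree (exactly 1 on a star phylogeny,
a closed-form identity the tests check); K < 1 means relatives resemble
each other less than Brownian motion predicts.  Significance permutes the
tip-to-row assignment (default 1000 permutations).  The univariate case
was cross-validated against an independent implementation in the R
phylogenetics ecosystem on a fixed 5-taxon fixture; the agreement values
are frozen into the test suite.

## Ancestral states, phylomorphospace, phenogram

Ancestral shapes are the per-dimension maximum-likelihood states under
Brownian motion, computed as the minimizer of Σ_edges ‖x_parent −
x_child‖²/length — a sparse linear system on the tree's branch-weighted
graph Laplacian.  Because the map from tip data to all node states is
linear, one factorization is reused across the thousands of simulated
datasets in the convergence null (this is the main performance lever).
The phylomorphospace projects ancestral states with the tip-derived
eigenvectors, so tips reproduce their PCA scores exactly.  The phenogram
is UPGMA (average linkage) on species-mean Procrustes distances,
hand-rolled so that the documented tie-break (lowest-index pair) is
guaranteed; it reproduces ultrametric inputs exactly and matches scipy's
average linkage on tie-free inputs in the tests.  The tanglegram screen
reports phenogram sister pairs whose patristic distance on the phylogeny
exceeds a configurable quantile (default median) of all pairwise tip
distances — a screening aid only; focal pairs for convergence testing
remain an analyst's choice.

## Convergence metrics

For a focal tip pair, with reconstructed states on the two paths from the
MRCA to the tips (tips and MRCA included): Dmax is the largest Euclidean
distance between any node of one lineage and any node of the other, Dtip
the tip-tip distance, C1 = 1 − Dtip/Dmax, C2 = Dmax − Dtip,
C3 = C2/L_lineage (total change along both focal paths), C4 = C2/L_clade
(total change along every edge below the MRCA).  Dmax uses node states
only — no along-branch interpolation or time synchronization — which is
the method's main approximation.  C5 (convergence frequency) is out of
scope.

p-values simulate Brownian motion on the same tree with the rate matrix
R = (Y−1a)′C⁻¹(Y−1a)/(n−1) estimated from the tip data (a scalar-rate
mode, σ²I with σ² the mean per-variable rate, is available).  R is
rank-deficient when variables outnumber species; simulation uses its
eigendecomposition and keeps zero-variance directions exactly zero rather
than regularizing.  The standard normal draws are taken before R is
factored in, so rescaling R leaves scale-free statistics (C1) unchanged
under the same seed.  Each metric's p is the proportion of simulations
reaching at least the observed value, observed included — never 0.

Two calibration facts worth knowing.  First, C1 has a point mass at 0
under divergent Brownian motion (the tip-tip distance usually *is* the
lineage maximum), so the tie-inclusive p cannot be uniform under the null:
it is conservative, with an atom near 1.  The exact-uniformity check in
the tests therefore uses the tie-randomized Monte-Carlo p computed from
the simulated distribution (returned in `sim_values`), which is exactly
U(0,1) under exchangeability.  Second, estimating a full rate matrix from
as many variables as species makes the null slightly conservative; the
calibration test uses the scalar-rate mode, which matches its isotropic
generating process.

## Synthetic data

The generator emulates a comparative skull-shape study: a pure-birth tree
with a fixed number of tips, scaled to unit root-to-tip depth; species
mean shapes evolved by Brownian motion from a bilaterally symmetric
17-landmark template (6 bilateral pairs + 5 midline points, ~60 mm long);
optional habitat effects along one fixed unit direction (multipliers
marine +1, brackish 0, fresh −1); optional forced convergence pulling a
tip pair toward its midpoint by a weight in [0, 1] (weight 1 → identical
tips); specimens as species means plus symmetric and asymmetric digitizing
noise; optional replicate measurements; landmarks masked independently at
a small missing rate (never below 4 present).

Defaults mirror the emulated study dimensions: 28 species, 9 specimens per
species, replicate error 0.38 mm (digitizer accuracy), missing rate 0.005,
Brownian rate 2 mm² per unit depth per coordinate (chosen so that, after
scaling by a centroid size of ~100 mm, the specimen-level Procrustes
variance lands near 0.01, the magnitude typical of congeneric skull
datasets).

Species means are kept *exactly* bilaterally symmetric: Brownian
increments and the habitat direction are drawn in the symmetric subspace
of the symmetry map (paired landmarks get mirrored increments; midline
landmarks get no increment along the reflection axis).  Real data are
analysed through their symmetric component anyway, and the choice makes
the symmetric/asymmetric decomposition of simulated specimens exact.  The
consequence — midline landmarks have zero mean-shape variance along the
reflection axis — is why variance-law checks use unconstrained
coordinates.  Specimen noise is decomposed the same way: the symmetric
part mirrors across pairs, the asymmetric part anti-mirrors, so the two
are orthogonal by construction.

What the generator does **not** emulate: skull biomechanics or integration
(increments are isotropic across landmarks), Ornstein-Uhlenbeck adaptation
(convergence is a geometric midpoint pull, not a selective regime),
digitizer orientation jitter (configurations are generated in a common
frame; the superimposition tests add random similarity transforms
explicitly), and allometry (no size-shape covariance).  Passing tests
demonstrate the statistical machinery is correct and calibrated under
these conditions; they do not certify behaviour under strong integration
or model misspecification.

## Problem sizes

Simulation-backed tests use deliberately small, fixed-seed problem sizes
chosen for tight Monte-Carlo resolution at interactive runtimes: 200
Brownian-motion replicates for the K calibration (20 trait dimensions on a
28-tip tree), 200 null datasets for the RRPP type-I check (199
permutations each), 100 paired replicates for the ordinary-vs-phylogenetic
ANOVA contrast, and 200 replicates × 200 simulations for the C1
calibration.  The full suite runs in well under a minute on one core.

## Known limitations

* GPA with object symmetry assumes one dataset-wide symmetry map; per-
  specimen maps (e.g. damaged sides) are not supported.
* The tanglegram screen only nominates *sister* pairs of the phenogram;
  convergent triplets or paraphyletic clusters must be supplied manually
  as focal pairs.
* Ancestral states (and hence the C-metrics) assume homogeneous-rate
  Brownian motion; rate shifts bias Dmax downward on fast branches.
* The measurement-error design is the two-level individual/replicate
  model; nested digitizer/session terms are not implemented.
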