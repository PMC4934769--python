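# Methods

This document describes the statistical model behind `morphodiet`, the
defaults it ships with and why, and what the synthetic generators do and do
not emulate.

## 1. Landmark data and superimposition

Configurations are 2-D landmark sets read from TPS files (`LM=`, optional
`SCALE=`, `ID=`, `IMAGE=`, `CURVES=`/`POINTS=` blocks for outline
semi-landmarks).  An optional CSV sidecar supplies per-specimen metadata
(phase, site, status, dental stage).

**Centroid size** is the square root of the summed squared distances of the
points to their centroid; it is the size variable throughout.

**Generalized Procrustes analysis (GPA)** removes position, scale and
orientation: each configuration is centered, scaled to unit centroid size,
and rotated onto the running consensus by the Kabsch solution constrained to
proper rotations (no reflections by default; `allow_reflection=True` lifts
the constraint).  The consensus is re-estimated and the fit iterated to a
consensus-change tolerance of 1e-10.  Alignment of similarity-transformed
copies of a shape reaches zero pairwise distance to better than 1e-9.

**Bending energy.** For a reference configuration the thin-plate-spline
kernel `U(r) = r² log r²` builds `L = [[K, Q], [Qᵀ, 0]]`; the bending-energy
matrix is the top-left `k×k` block of `L⁻¹`.  It is positive semi-definite
and annihilates affine transforms of the reference; coincident landmarks
raise `SingularKernelError`.

**Semi-landmark sliding.** Semi-landmarks slide along outline tangents
(central differences over the cyclic neighbor structure) to minimize total
bending energy against the consensus; the per-specimen sliding amounts are
the exact least-squares solution, after which the sample is re-superimposed
and the consensus recomputed.  Within a pass the energy can only decrease
(this is asserted property-based in the tests).  Because sliding and
re-superimposition alternate, the mean displacement plateaus rather than
contracting geometrically; the default tolerance is 1e-6 with 10 passes, and
on non-convergence the last state is returned flagged `converged=False` with
a `RuntimeWarning` — it is still a valid superimposition, just not a fixed
point at that tolerance.

## 2. Shape statistics

**PCA** of the aligned coordinates (eigendecomposition of the covariance)
supplies the variables for all downstream tests; total variance is conserved
to 1e-10.

**Allometry.** The association between shape and log centroid size is the
percentage of shape variance predicted by the multivariate regression on
log size; significance is a permutation test of that statistic with the
add-one convention (`p = (b + 1)/(n_perm + 1)`, never zero).  Default
`n_perm=1000`.  The type-I error of this test is calibrated: over 500 null
simulations the rejection rate at α = 0.05 falls inside the 95% binomial
band.  When significant, the **pooled within-group correction** regresses
shape on log size within groups (singleton groups are excluded with a
warning) and analyses proceed on residuals, which preserve group means and
are exactly orthogonal to log size within groups.

**MANOVA** (Pillai trace and Wilks' Λ with F approximations) is computed
from the eigenvalues of `E⁻¹H` on the leading principal components; a
singular within-group matrix raises an error advising reduction to fewer
principal components.  Results match `statsmodels`' MANOVA on the same data.

**CVA.** Canonical variates come from the generalized eigenproblem of the
between- and pooled within-group covariances, scaled so the pooled
within-group covariance of the scores is the identity (to 1e-6).
Mahalanobis distances between group means are therefore Euclidean in score
space, invariant to invertible linear transforms of the input at full rank,
and recover planted two-Gaussian separations within sampling error.
Classification accuracy is leave-one-out LDA.  The number of principal
components entering CVA is chosen by `select_pc_count`: bootstrap the LOO
accuracy over candidate counts and take the smallest count within one
standard error of the plateau, capped at `min(group n) − 1`.

**Phenogram.** Mahalanobis distances feed a hand-rolled neighbor-joining
algorithm (lowest-(i,j) tie-break on the Q matrix, negative branch lengths
clamped to zero with a warning, 3-taxon closed form).  On additive matrices
NJ reproduces the unique generating tree exactly — verified against a
brute-force topology enumeration with least-squares branch fitting for up to
7 taxa.

**Confidence ellipses** use the chi-square radius for the requested level on
the group covariance; rank-deficient groups are flagged degenerate.

## 3. Mixture models and the admixture screen

`fit_gmm` is a seeded EM implementation with k-means++ initialization, 5
restarts, and up to 3 jittered retries on component collapse.  One-dimensional
families: `E` (equal variance, `df = 2G`) and `V` (per-component variance,
`df = 3G − 1`); multivariate families combine {spherical, diag, full} ×
{equal, variable}.  Model choice maximizes `BIC = 2L − df·ln n` (higher is
better); e.g. `bic_score(−44.25, 4, 17) = −99.83`.

`cluster_d13C` applies this to collagen δ13C with `G ∈ {1, 2, 3}` and the
equal-variance family by default.  The equal-variance assumption can
over-split one wide plus one tight mode; passing `families=("E", "V")`
resolves such cases.  On the bimodal 17-specimen Longshan-range preset the
default selects `G = 2` in ≥ 80% of seeded replicates.

`admixture_screen` looks for wild/domestic mixtures within a nominal group:
it fits mixtures to per-specimen log centroid size (optionally joined with
leading shape PCs), selects G by BIC, and flags groups whose best model has
G ≥ 2 with a component mean inside the supplied wild log-size range (any
second mode flags when no range is given).  Groups under 5 specimens are
skipped.  Detection power is driven by the size gap in units of the
within-mode SD: at the realistic wild/domestic contrast (centroid sizes 95
vs 62, log SD 0.08 — a ≈5σ gap) the screen attains perfect
sensitivity/specificity over 50 replicates at assemblage-scale group sizes;
at a 3σ gap single-dataset power is only ≈50%, so absence of a flag is not
evidence of purity.

## 4. Isotope diet model

All δ13C in ‰ VPDB, δ15N in ‰ AIR.

- **Fossil-fuel (Suess) correction**: modern plant values get +1.5‰ before
  comparison with archaeological collagen; archaeological plant values do
  not.
- **Diet-to-collagen enrichment**: +5‰.
- **Endmembers** (collagen equivalents): pure C3 (−22.5, −18.5)‰ with mean
  −20‰; millet seed (−6.9, −4.6)‰ from archaeological seed (−11.9, −9.6)‰;
  millet leaf (−8.1, −5.8)‰ from modern leaf (−14.6, −12.3)‰.
- **δ13C classes**: ≤ −25 forest-C3 contribution; < −18.5 pure C3; ≥ −8.1
  C4 dominant; otherwise mixed C3/C4.  The *indicative* millet fraction is a
  linear two-endmember mixing estimate between the C3 collagen mean (−20‰)
  and the pooled millet collagen mean, clamped to [0, 100] — indicative
  because it ignores protein routing and within-diet variance.
- **Trophic banding** compares δ15N to site-specific herbivore/carnivore
  baselines by nearest anchor, with an intermediate omnivore band.
- **M3 length** classifies wild vs domestic at a strict 37.9 mm cutoff
  (≥ cutoff → wild is *not* used; values above the cutoff are wild,
  the cutoff itself domestic).
- **Weaning filter**: specimens below dental stage 10 are removed before
  diet inference (strict mode also drops unknown stages), because suckling
  animals carry a trophic-level offset.

Per-phase comparisons use one-way ANOVA on δ13C and δ15N, with ranges
reported when only one phase is present.

## 5. Synthetic data

The generators exist to give every routine a ground truth, not to imitate
any particular assemblage:

- the template is a bilobed molar-like outline `r = 1 + 0.35·cos 2θ` with 2
  fixed landmarks and arc-length-uniform semi-landmarks;
- deformations use three orthonormal canonical fields (drift, divergent,
  allometry); shape = template + group deformation + allometric term
  `slope·(log CS − mean)·field` + isotropic landmark noise; sizes are
  lognormal; configurations are then randomly rotated/translated/scaled;
- the isotope generator draws per-phase Gaussian-mixture δ13C (optionally
  tying M3 length to mixture component) and Gaussian δ15N.

Known, intentional simplifications: no digitizing-error covariance
structure, no outline self-occlusion, no correlation between shape noise and
size, no isotope seasonality, and the divergent deformation is only
approximately orthogonal to the drift axis after projection to shape space
(a small leak of the divergent phase into CV1 is expected).

## 6. Defaults

| parameter | default | rationale |
| --- | --- | --- |
| GPA tolerance | 1e-10 | machine-precision consensus; cheap at these sizes |
| sliding tol / passes | 1e-6 / 10 | displacement plateaus near 1e-6; flagged, not fatal |
| allometry permutations | 1000 | p-resolution 1e-3; calibrated type-I error |
| allometry α | 0.05 | standard; gates the pooled correction in the pipeline |
| mixture G range | 1–3 | one, split, or split-plus-outlier regimes |
| mixture family | `E` | stable at n ≈ 15–50 typical of phase samples |
| BIC convention | `2L − df·ln n`, higher better | matches the reported mixture audit numbers |
| M3 cutoff | 37.9 mm | wild/domestic discriminant for pig lower M3 |
| weaning stage | ≥ 10 | post-weaning collagen only |
| CVA PC cap | `min(group n) − 1` | keeps pooled within-group covariance invertible |

## 7. Limitations

- Sliding is a block-coordinate descent; it guarantees within-pass energy
  decrease, not convergence to the global optimum.
- The admixture screen is a size-led univariate/low-dimensional BIC test;
  modest (≲3σ) size gaps are underpowered at archaeological sample sizes.
- The millet fraction is a two-endmember linear indicator, not a Bayesian
  mixing model; do not propagate it as a quantitative diet estimate.
- MANOVA F approximations assume multivariate normality of PC scores;
  permutation MANOVA is not implemented.
- All routines are 2-D; 3-D landmark support would require generalizing the
  TPS kernel and rotation fitting.
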