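# Methods

This note documents the statistical model behind `fdgm`, the choices
made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Shape model and alignment

A specimen is an ordered sequence of N 2D landmarks; its *shape* is
the equivalence class of that configuration under translation,
rotation and scaling.  GPA estimates a consensus shape and aligned
(Procrustes) coordinates by alternating two block updates that both
minimise the summed squared distance to the consensus:

* each unit-size, centred configuration is rotated onto the consensus
  by the orthogonal-Procrustes solution, constrained to proper
  rotations (det +1) so anatomical views are never mirrored;
* the consensus is the renormalised mean of the aligned
  configurations — which is exactly the constrained minimiser over
  unit-size shapes, so the objective is monotonically non-increasing
  (this is asserted by a test).

Full Procrustes scaling (every configuration fixed to unit centroid
size) is used throughout.  Convergence is declared when the consensus
moves by less than `tol = 1e-8` RMS (configurable); the consensus is
initialised from the first configuration, which only fixes the
arbitrary global rotation.  Procrustes coordinates are used directly —
no tangent-space projection — so the PCA baseline operates on the same
coordinates as the functional branch.

## Functional representation

Landmark digitisation order is the only ordering the data define, so
the functional domain is the landmark index mapped uniformly onto
[0, 1] (an arc-length parameterisation along the consensus is
available but not the default).  With smoothing off — the default —
the embedding is lossless: curve values are the aligned coordinates,
and the data-driven FPCA basis acts as the smoother.  Optional
B-spline least-squares smoothing (clamped uniform knots, order 4 by
default) is provided for noisy inputs; at `n_basis = N` it reproduces
the raw values, which is tested against a normal-equations oracle.
The L2 inner product is discretised by trapezoidal quadrature, whose
weights sum to the domain length 1 and are exact for piecewise-linear
integrands.

No curve registration/warping is applied: landmarks are already in
correspondence across specimens, so warping the domain would destroy
the correspondence the data provide.

## Univariate and multivariate FPCA

Univariate FPCA diagonalises the quadrature-weighted sample covariance
through the symmetrised route: eigenvectors of W^{1/2} K W^{1/2} are
mapped back by W^{-1/2}, making eigenfunctions orthonormal in the
weighted inner product and score variances equal to the eigenvalues.
All covariances use the n−1 divisor.

The multivariate step stacks the per-element scores into Ξ (element
order fixed), eigendecomposes Ẑ = ΞᵀΞ/(n−1), and maps eigenvectors
back to multivariate eigenfunctions and scores.  Two exactness
properties anchor the implementation and are tested against
independent dense-matrix oracles:

* with full univariate retention, the multivariate eigenvalues and
  scores equal those of weighted PCA of the concatenated curves;
* the full-retention Karhunen–Loève truncation reconstructs the
  centred curves to numerical precision, with diagonal score
  covariance.

Truncation: each univariate block retains the smallest number of
components reaching a cumulative eigenvalue fraction of
`pve_threshold` (default 0.99); the multivariate step keeps all
numerically nonzero eigenvalues (relative tolerance 1e-10) unless
`n_components` is given.  Variance-explained denominators use all
numerically nonzero eigenvalues.  Eigenvector signs follow one
deterministic convention — largest-magnitude entry positive, ties
broken at the lowest index — so repeated runs are bit-identical.
Among numerically equal eigenvalues only the spanned subspace is
identified, not the individual basis vectors.

## Discrimination and classification

LDA acts on the first K = 3 score columns (configurable) of either
branch.  The between-scatter is computed in the outer-centred form
(GH − 1ρ̄ᵀ)ᵀ(GH − 1ρ̄ᵀ)/(M−1), the only form that is symmetric
positive semidefinite; the within-scatter uses divisor n−M.  The
generalised problem B a = λ W a is solved by the symmetric-definite
routine, with a ridge fallback (ε = 1e-8 · trace(W)/K) if W is
singular.  Axes are unit-normalised; separation percentages are
100·λ_i/Σλ over the min(K, M−1) retained axes.

The classification protocol draws a stratified 70:30 split per
replicate (per-class train count = round(0.7·n_c) clamped to
[1, n_c−1]), shares the split across classifiers within a replicate
for a paired comparison, and reports mean and sample sd (divisor
reps−1) of plain test accuracy over 20 replicates.  Scores enter the
classifiers unstandardised — PC scores are already variance-ordered.

Classifier defaults where the protocol leaves them open: SVM C = 1
with `scale` kernel width (γ = 1/(K·Var(x)); the 1/(2σ²) form can be
passed explicitly); random forest with 500 trees and √K features per
split; elastic-net GLM with mixing α = 0.5 and penalty strength chosen
by stratified cross-validation on the training set only (5 folds,
capped at the smallest training class).  Naive Bayes uses Gaussian
class-conditional densities with maximum-likelihood variances and a
1e-9 variance floor for constant features; it is implemented in this
package because its posterior contract (exact normalisation,
closed-form two-class case) is part of the tested surface, whereas the
SVM, forest and GLM are scikit-learn estimators behind this module's
interface.

## Synthetic generator

The generator emulates a multi-species landmark study: class templates
on a perturbed-ellipse outline (so index order is geometrically
meaningful); specimen = template + isotropic per-landmark Gaussian
noise (σ_L); per-specimen random similarity transform; R digitisation
replicates with independent noise (σ_D) added in shape space before
the transform, so replicate error is scale-consistent.  Class
templates differ along smooth displacement fields orthogonal to the
similarity directions, placed on a regular simplex and rescaled until
every pairwise full Procrustes distance is within 2% of the requested
separation δ.

Defaults mirror the study conditions the toolkit is designed around:
3 classes of 29/30/30 specimens, 3 replicates, views of 25/50/47
landmarks, δ = 0.2, σ_L = 0.02, σ_D = 0.01 (shape units).  The noise
scales are not published quantities; they were chosen once as a
plausible digitisation-error regime in which δ/σ_L = 10, matching the
near-perfect classification the score-based protocol achieves on
well-separated species.  What the generator does **not** emulate:
allometry (size–shape covariation), correlated landmark noise along
outlines, view-to-view dependence within a specimen, unbalanced or
missing replicates, and digitisation outliers.  Passing tests
therefore demonstrate correctness of the estimators and the expected
qualitative behaviour (accuracy rising with separation-to-noise,
chance level at δ = 0), not performance on real skull data.

## Numerical and scale choices

* Eigenvalues below 1e-10 of the largest are treated as zero
  everywhere (rank decisions, PVE denominators).
* Replicate averaging sums coordinates in a canonical sorted order and
  returns the common value exactly where replicates agree, making the
  average exactly invariant to replicate ordering.
* Test and acceptance runs use moderate problem sizes (≈ 90 specimens,
  12–50 landmarks, 20 split replicates), the sizes at which the
  protocol's accuracy estimates are stable to well under the reported
  sd.
* TPS SCALE factors are parsed but not applied by default: GPA removes
  size, so physical units are irrelevant downstream.

## Known limitations

Strictly 2D landmarks (3D TPS records are rejected); no sliding of
semilandmarks (type annotations are carried but not acted on); no
tangent-space projection; no missing-landmark estimation; the
functional domain assumes a common landmark scheme across specimens.
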