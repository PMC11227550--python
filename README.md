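# fdgm — functional-data geometric morphometrics

`fdgm` is a Python toolkit for landmark-based statistical shape analysis
that treats each specimen's landmark configuration as a pair of curves
rather than a vector of coordinates.  It is aimed at morphometricians
classifying taxa (e.g. shrew species from craniodental landmarks) who
want to compare the classical geometric-morphometrics (GM) pipeline
with a functional-data alternative on the same data.

## The method

Starting from 2D landmark configurations digitised in a fixed order
(several digitisation replicates per specimen), the pipeline is:

1. **Replicate averaging.** Per-landmark arithmetic mean over the R
   digitisation replicates of each specimen.
2. **Generalised Procrustes analysis (GPA).** Translation, scale and
   rotation are removed by iterative superimposition: every
   configuration is centred, scaled to unit centroid size and rotated
   (proper rotations only) onto the consensus, which is re-estimated
   until convergence.
3. **Functional representation.** The aligned x- and y-coordinates of
   specimen *i* become two curves X⁽ⁱ⁾(t), Y⁽ⁱ⁾(t) sampled on the
   landmark-index grid t_j = (j−1)/(N−1) ⊂ [0, 1], with trapezoidal
   quadrature weights.  For V views combined, the specimen is a
   d = 2V-element multivariate functional datum.
4. **Multivariate functional PCA (MFPCA).** Univariate FPCA per
   element gives scores ψ_{p,j}; these are stacked into Ξ ∈ ℝ^{n×J}
   and the block score-covariance **Ẑ** = ΞᵀΞ/(n−1) is
   eigendecomposed.  Eigenvectors v̂_j weight the univariate
   eigenfunctions into multivariate eigenfunctions φ̂_{p,j}, and
   ξ̂_j⁽ⁱ⁾ = Ξᵢ·v̂_j are the multivariate scores.  The GM baseline is
   ordinary PCA of the flattened Procrustes coordinates.
5. **Discrimination and classification.** The first K = 3 scores feed
   (a) linear discriminant analysis with explicit scatter matrices
   W = (ρ−GH)ᵀ(ρ−GH)/(n−M) and B = (GH−1ρ̄ᵀ)ᵀ(GH−1ρ̄ᵀ)/(M−1),
   whose generalised eigenvalues give per-axis separation
   percentages, and (b) four classifiers — Gaussian naive Bayes,
   RBF-kernel SVM (one-vs-one), random forest, multinomial
   elastic-net GLM — evaluated by mean ± sd test accuracy over 20
   stratified 70:30 splits.

A synthetic generator produces landmark studies with known class
structure (class templates at a calibrated Procrustes distance,
per-landmark noise, random similarity transforms, digitisation
replicates) so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from fdgm import (SimulationSpec, simulate_dataset, average_replicates, gpa,
                  to_functional, mfpca, classical_pca, lda_fit, evaluate_protocol)

spec = SimulationSpec(n_landmarks=25, n_per_class=(29, 30, 30), seed=7)
replicates, truth = simulate_dataset(spec)
aligned = gpa(average_replicates(replicates))
print(f"GPA converged in {aligned.iterations_used} iterations")

fdgm_result = mfpca(to_functional(aligned), pve_threshold=0.99)
gm_result = classical_pca(aligned)
print(f"MFPCA: {fdgm_result.n_components} components, "
      f"first two explain {100 * fdgm_result.pve[1]:.2f}% of variance")
print(f"GM PCA: {gm_result.n_components} components, "
      f"first two explain {100 * gm_result.pve[1]:.2f}%")

labels = np.array(truth["labels"])
lda = lda_fit(fdgm_result.scores[:, :3], labels)
print("LDA separation: "
      + ", ".join(f"{p:.2f}%" for p in lda.separation_percentages))

report = evaluate_protocol(fdgm_result.scores[:, :3], labels, reps=20, seed0=7)
for name in report.classifier_names:
    print(f"{name}: {report.mean_accuracy(name):.3f} "
          f"({report.sd_accuracy(name):.3f})")
```

Output:

```
GPA converged in 4 iterations
MFPCA: 45 components, first two explain 43.25% of variance
GM PCA: 47 components, first two explain 43.02%
LDA separation: 57.08%, 42.92%
NB: 1.000 (0.000)
SVM: 1.000 (0.000)
RF: 1.000 (0.000)
GLM: 1.000 (0.000)
```

This simulates one 25-landmark view of three species (29/30/30
specimens, three digitisation replicates).  At the default
separation-to-noise ratio of 10 the three classes are cleanly
separable, so all four classifiers reach perfect test accuracy; the
two leading discriminant axes split the between-class structure
roughly evenly because the three class templates sit at the corners
of a near-equilateral triangle in shape space.

## Command line

```sh
fdgm simulate --out data/            # synthetic three-view study (TPS + manifest)
fdgm average --manifest data/manifest.csv --view dorsal --out dorsal.tps
fdgm gpa dorsal.tps --out gpa_out/
fdgm mfpca dorsal.tps --labels labels.csv --out scores/
fdgm lda scores/mfpca_scores.csv --out lda_out/
fdgm classify scores/mfpca_scores.csv --seed 1 --out report.json
fdgm run-all --seed 1 --out results/     # full GM-vs-FDGM comparison
```

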