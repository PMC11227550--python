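"""Functional and classical principal component decompositions.

Three estimators live here:

* :func:`ufpca` — univariate FPCA of one functional element.  The
  quadrature-weighted sample covariance operator is diagonalised via
  the symmetrised ``W^{1/2} K W^{1/2}`` route, which makes the
  eigenfunctions orthonormal in the weighted L2 inner product and the
  scores' sample variances equal to the eigenvalues.

* :func:`mfpca` — multivariate FPCA built from the univariate blocks:
  stack the univariate scores into a matrix Xi (n x J), form the block
  score-covariance Z = Xi' Xi / (n-1), eigendecompose Z, and map each
  eigenvector back to a multivariate eigenfunction by weighting the
  univariate eigenfunctions.  Multivariate scores are Xi v_j.  When
  every univariate block retains all of its variance this estimator is
  exact: it reproduces the weighted PCA of the concatenated curves.

* :func:`classical_pca` — ordinary PCA of the flattened Procrustes
  coordinates (the geometric-morphometrics baseline).

All covariances use the n-1 divisor.  Eigenvector signs follow one
deterministic convention — the entry of largest magnitude is made
positive, ties broken by lowest index — so repeated runs are bit-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .functional import FunctionalDataset
from .landmark_io import ValidationError
from .procrustes import AlignedDataset

RANK_TOL = 1e-10  # eigenvalues below RANK_TOL * max are numerically zero


class UsageError(ValueError):
    pass


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties are broken by the lowest index (argmax of the absolute value).
    """
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _nonzero_count(eigenvalues: np.ndarray) -> int:
    if eigenvalues.size == 0 or eigenvalues[0] <= 0:
        return 0
    return int(np.sum(eigenvalues > RANK_TOL * eigenvalues[0]))


@dataclass
class UnivariateFPCAResult:
    """FPCA of a single functional element."""

    mean_function: np.ndarray  # (N,)
    eigenfunctions: np.ndarray  # (J, N), rows orthonormal under quadrature
    eigenvalues: np.ndarray  # (J,), non-increasing
    scores: np.ndarray  # (n, J)
    grid: np.ndarray
    weights: np.ndarray
    all_eigenvalues: np.ndarray  # full nonzero spectrum, for PVE denominators

    @property
    def n_retained(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class MFPCAResult:
    """Multivariate FPCA assembled from univariate blocks."""

    univariate: list[UnivariateFPCAResult]
    element_names: list[str]
    score_matrix: np.ndarray  # Xi, (n, J)
    block_cov: np.ndarray  # Z-hat, (J, J)
    eigenvalues: np.ndarray  # (J_kept,), non-increasing
    eigenvectors: np.ndarray  # (J, J_kept), orthonormal columns
    eigenfunctions: list[np.ndarray]  # per element: (J_kept, N_p)
    scores: np.ndarray  # (n, J_kept)
    pve: np.ndarray  # cumulative proportion of variance
    specimen_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]

    def block_slices(self) -> list[slice]:
        """Column ranges of Xi belonging to each element's block."""
        slices, start = [], 0
        for u in self.univariate:
            slices.append(slice(start, start + u.n_retained))
            start += u.n_retained
        return slices


@dataclass
class PCAResult:
    """Classical PCA of flattened Procrustes coordinates."""

    mean: np.ndarray
    loadings: np.ndarray  # (k, 2N) rows
    eigenvalues: np.ndarray
    scores: np.ndarray  # (n, k)
    pve: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]


def ufpca(
    values: np.ndarray,
    grid: np.ndarray,
    weights: np.ndarray,
    pve_threshold: float = 0.99,
    n_components: int | None = None,
) -> UnivariateFPCAResult:
    """Univariate FPCA of curves sampled on a common grid.

    Parameters
    ----------
    values : (n, N) array
        One curve per row.
    grid, weights : (N,) arrays
        Sampling points and quadrature weights.
    pve_threshold : float in (0, 1]
        Retain the smallest number of components whose cumulative
        eigenvalue fraction (of the numerically nonzero spectrum)
        reaches the threshold.
    n_components : int, optional
        Overrides the threshold rule.
    """
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValidationError(f"expected an (n, N) matrix, got shape {values.shape}")
    n = values.shape[0]
    if n < 3:
        raise ValidationError("FPCA needs at least 3 curves")
    if not (0 < pve_threshold <= 1):
        raise UsageError(f"pve_threshold must be in (0, 1], got {pve_threshold}")
    weights = np.asarray(weights, float)
    grid = np.asarray(grid, float)

    mean = values.mean(axis=0)
    centred = values - mean
    cov = centred.T @ centred / (n - 1)
    sqrt_w = np.sqrt(weights)
    sym = sqrt_w[:, None] * cov * sqrt_w[None, :]
    sym = (sym + sym.T) / 2
    eigval, eigvec = np.linalg.eigh(sym)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    n_nonzero = _nonzero_count(eigval)
    if n_nonzero == 0:
        warnings.warn("zero-variance element; retaining one null component", RuntimeWarning)
        n_keep = 1
    elif n_components is not None:
        if n_components < 1 or n_components > eigval.size:
            raise UsageError(f"n_components must be in [1, {eigval.size}]")
        n_keep = n_components
    else:
        fractions = np.cumsum(eigval[:n_nonzero]) / eigval[:n_nonzero].sum()
        n_keep = int(np.searchsorted(fractions, pve_threshold - 1e-12) + 1)

    eigvec = _fix_signs(eigvec[:, :n_keep])
    # Map back from the symmetrised domain: phi = W^{-1/2} u.
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(sqrt_w[:, None] > 0, eigvec / sqrt_w[:, None], 0.0).T
    scores = centred @ (weights[:, None] * phi.T)
    return UnivariateFPCAResult(
        mean_function=mean,
        eigenfunctions=phi,
        eigenvalues=eigval[:n_keep],
        scores=scores,
        grid=grid,
        weights=weights,
        all_eigenvalues=eigval[:max(n_nonzero, 1)],
    )


def mfpca(
    fd: FunctionalDataset,
    pve_threshold: float = 0.99,
    n_components: int | None = None,
) -> MFPCAResult:
    """Multivariate FPCA of a d-element functional dataset.

    Runs :func:`ufpca` per element with the shared ``pve_threshold``,
    stacks the scores into Xi in element order, forms the block
    covariance Z = Xi' Xi / (n-1), and eigendecomposes it.  The
    multivariate eigenfunction's element p for component j is the
    eigenvector-weighted combination of element p's univariate
    eigenfunctions; the multivariate score is Xi v_j.
    """
    uni = [
        ufpca(el.values, el.grid, el.weights, pve_threshold=pve_threshold)
        for el in fd.elements
    ]
    xi = np.hstack([u.scores for u in uni])
    n, total_j = xi.shape
    z = xi.T @ xi / (n - 1)
    z = (z + z.T) / 2
    eigval, eigvec = np.linalg.eigh(z)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_signs(eigvec[:, order])

    n_nonzero = _nonzero_count(eigval)
    denom = eigval[: max(n_nonzero, 1)].sum()
    if n_components is not None:
        if n_components > total_j:
            raise UsageError(
                f"requested {n_components} components but only {total_j} are available"
            )
        n_keep = n_components
    else:
        n_keep = max(n_nonzero, 1)
    eigval = eigval[:n_keep]
    eigvec = eigvec[:, :n_keep]

    # Per-element multivariate eigenfunctions.
    eigenfunctions = []
    start = 0
    for u in uni:
        block = eigvec[start : start + u.n_retained, :]  # (J_p, J_kept)
        eigenfunctions.append(block.T @ u.eigenfunctions)  # (J_kept, N_p)
        start += u.n_retained
    scores = xi @ eigvec
    pve = np.cumsum(eigval) / denom if denom > 0 else np.zeros_like(eigval)

    return MFPCAResult(
        univariate=uni,
        element_names=fd.element_names,
        score_matrix=xi,
        block_cov=z,
        eigenvalues=eigval,
        eigenvectors=eigvec,
        eigenfunctions=eigenfunctions,
        scores=scores,
        pve=pve,
        specimen_ids=list(fd.specimen_ids),
        labels=list(fd.labels),
    )


def classical_pca(
    aligned: AlignedDataset | np.ndarray,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the flattened (n, 2N) Procrustes coordinate matrix.

    Covariance-form PCA with the n-1 divisor; components whose
    eigenvalue is numerically zero (below ``1e-10`` of the largest) are
    dropped, so at most min(n-1, 2N) components are returned.
    """
    if isinstance(aligned, AlignedDataset):
        matrix = aligned.flattened()
        specimen_ids = aligned.specimen_ids
        labels = aligned.labels
    else:
        matrix = np.asarray(aligned, float)
        specimen_ids = [f"row_{i}" for i in range(matrix.shape[0])]
        labels = [""] * matrix.shape[0]
    n = matrix.shape[0]
    if n < 3:
        raise ValidationError("PCA needs at least 3 specimens")
    mean = matrix.mean(axis=0)
    centred = matrix - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    all_eigval = s**2 / (n - 1)
    n_nonzero = _nonzero_count(all_eigval)
    denom = all_eigval[: max(n_nonzero, 1)].sum()
    if n_components is not None:
        if n_components > all_eigval.size:
            raise UsageError(
                f"requested {n_components} components but only {all_eigval.size} exist"
            )
        n_keep = n_components
    else:
        n_keep = max(n_nonzero, 1)
    eigval = all_eigval[:n_keep]
    loadings = _fix_signs(vt[:n_keep].T).T
    scores = centred @ loadings.T
    pve = np.cumsum(eigval) / denom if denom > 0 else np.zeros_like(eigval)
    return PCAResult(
        mean=mean,
        loadings=loadings,
        eigenvalues=eigval,
        scores=scores,
        pve=pve,
        specimen_ids=list(specimen_ids),
        labels=list(labels),
    )


def pve(eigenvalues: np.ndarray, k: int) -> float:
    """Proportion of variance explained by the first k components.

    The denominator is the sum of all numerically nonzero eigenvalues.
    """
    eigenvalues = np.asarray(eigenvalues, float)
    if k < 1 or k > eigenvalues.size:
        raise UsageError(f"k must be in [1, {eigenvalues.size}], got {k}")
    n_nonzero = _nonzero_count(eigenvalues)
    if n_nonzero == 0:
        raise UsageError("all eigenvalues are zero; proportion of variance undefined")
    total = eigenvalues[:n_nonzero].sum()
    return float(eigenvalues[:k].sum() / total)


def reconstruct(result: MFPCAResult, element: int) -> np.ndarray:
    """Karhunen-Loeve reconstruction of one element's centred curves.

    Sum over components of score times eigenfunction; with all
    components kept and full univariate retention this reproduces the
    centred data exactly.
    """
    return result.scores @ result.eigenfunctions[element]
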