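"""Linear discriminant analysis on principal component scores.

Discrimination happens in score space: the first K (default 3)
principal component scores — classical PC scores for the
geometric-morphometrics branch, multivariate FPC scores for the
functional branch — enter the same score-based LDA.  Scatter matrices
use explicit divisors:

    W = (rho - G H)' (rho - G H) / (n - M)      within-class
    B = (G H - 1 rho_bar')' (G H - 1 rho_bar') / (M - 1)   between-class

with rho the n x K score matrix, G the n x M one-hot class indicator,
H the M x K class-mean matrix and rho_bar the grand mean.  Discriminant
axes maximise a'Ba / a'Wa, i.e. solve the generalised eigenproblem
B a = lambda W a; at most min(K, M-1) axes carry discrimination.  Each
axis's eigenvalue as a share of the eigenvalue total is its separation
percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .decomposition import _fix_signs
from .landmark_io import ValidationError


class UsageError(ValueError):
    pass


@dataclass
class DiscriminantResult:
    within_scatter: np.ndarray  # (K, K)
    between_scatter: np.ndarray  # (K, K)
    class_means: np.ndarray  # (M, K)
    classes: list[str]
    indicator: np.ndarray  # (n, M) one-hot
    axes: np.ndarray  # (K, n_axes), unit-norm columns
    axis_eigenvalues: np.ndarray  # (n_axes,), non-increasing
    separation_percentages: np.ndarray  # sums to 100
    projected: np.ndarray  # (n, n_axes)
    grand_mean: np.ndarray  # (K,)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]


def lda_fit(scores: np.ndarray, labels) -> DiscriminantResult:
    """Fit score-based LDA with explicit within/between scatter matrices.

    Parameters
    ----------
    scores : (n, K) array
        Principal component scores (classical or multivariate
        functional), K >= 1.
    labels : sequence of n class labels
        At least two classes, each with at least two members.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2:
        raise ValidationError(f"scores must be (n, K), got shape {scores.shape}")
    n, k = scores.shape
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    m = len(classes)
    if m < 2:
        raise ValidationError("need at least two classes")
    if n <= m:
        raise ValidationError(f"need n > M, got n={n}, M={m}")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    small = [c for c, cnt in counts.items() if cnt < 2]
    if small:
        raise ValidationError(f"classes with fewer than 2 members: {small}")

    indicator = np.zeros((n, m))
    for j, c in enumerate(classes):
        indicator[labels == c, j] = 1.0
    class_means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    grand_mean = scores.mean(axis=0)

    fitted = indicator @ class_means  # G H: each row is its class mean
    residual = scores - fitted
    within = residual.T @ residual / (n - m)
    centred_fit = fitted - grand_mean
    between = centred_fit.T @ centred_fit / (m - 1)

    w_solve = within
    try:
        # eigh solves the symmetric-definite generalised problem B a = l W a.
        eigval, eigvec = linalg.eigh(between, w_solve)
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(within) / k
        warnings.warn(
            f"singular within-class scatter; adding ridge {ridge:.3e}",
            RuntimeWarning,
        )
        w_solve = within + ridge * np.eye(k)
        eigval, eigvec = linalg.eigh(between, w_solve)

    order = np.argsort(eigval)[::-1]
    n_axes = min(k, m - 1)
    eigval = np.clip(eigval[order][:n_axes], 0.0, None)
    axes = eigvec[:, order][:, :n_axes]
    axes = axes / np.linalg.norm(axes, axis=0, keepdims=True)
    axes = _fix_signs(axes)

    result = DiscriminantResult(
        within_scatter=within,
        between_scatter=between,
        class_means=class_means,
        classes=classes,
        indicator=indicator,
        axes=axes,
        axis_eigenvalues=eigval,
        separation_percentages=separation_percentages(eigval),
        projected=(scores - grand_mean) @ axes,
        grand_mean=grand_mean,
    )
    return result


def separation_percentages(axis_eigenvalues: np.ndarray | DiscriminantResult) -> np.ndarray:
    """Each discriminant axis's eigenvalue as a percentage of the total."""
    if isinstance(axis_eigenvalues, DiscriminantResult):
        axis_eigenvalues = axis_eigenvalues.axis_eigenvalues
    eigval = np.asarray(axis_eigenvalues, float)
    total = eigval.sum()
    if total <= 0:
        raise UsageError("all discriminant eigenvalues are zero; separation undefined")
    return 100.0 * eigval / total


def lda_project(result: DiscriminantResult, scores: np.ndarray) -> np.ndarray:
    """Project new score rows onto the fitted discriminant axes.

    Scores are centred by the training grand mean before projection, so
    the training mean maps to the origin.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[1] != result.grand_mean.shape[0]:
        raise UsageError(
            f"scores must have {result.grand_mean.shape[0]} columns, "
            f"got shape {scores.shape}"
        )
    return (scores - result.grand_mean) @ result.axes
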