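"""Generalised Procrustes analysis for 2D landmark configurations.

Shape is what remains of a landmark configuration once location,
orientation and size are removed.  GPA removes them across a whole
sample: every configuration is centred, scaled to unit centroid size
and rotated onto a consensus; the consensus is the (renormalised) mean
of the aligned configurations, and the two steps alternate until the
consensus stops moving.  Both block updates minimise the same
least-squares objective, so the objective is non-increasing.

Rotations are proper (determinant +1): anatomical views must never be
mirrored by the alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset, ValidationError


class DegenerateShapeError(ValueError):
    """All landmarks coincide; the configuration has no shape."""


@dataclass
class AlignedDataset:
    """GPA output: Procrustes coordinates plus size and consensus.

    Attributes
    ----------
    coords : ndarray (n, N, 2)
        Procrustes-aligned coordinates; each configuration is centred at
        the origin with unit centroid size.
    centroid_sizes : ndarray (n,)
        Centroid size of each configuration *before* scaling — the size
        variable removed by GPA.
    consensus : ndarray (N, 2)
        Procrustes mean shape, unit centroid size.
    objective_history : list of float
        Summed squared distances to the consensus after each iteration.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations_used: int
    converged: bool
    specimen_ids: list[str]
    labels: list[str]
    view: str = "other"
    objective_history: list[float] | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """Row-per-specimen (n, 2N) matrix: x1 y1 x2 y2 ... in landmark order."""
        return self.coords.reshape(self.n, -1)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: root of summed squared distances from the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size == 0.0:
        raise DegenerateShapeError("all landmarks coincide")
    return size


def _centre_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size == 0.0:
        raise DegenerateShapeError("all landmarks coincide")
    return centred / size, size


def optimal_rotation(reference: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||reference - moving @ R||_F.

    Both inputs are (N, 2) and assumed centred.  Reflections are
    excluded: the determinant of R is forced to +1.
    """
    m = moving.T @ reference
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def superimpose(reference: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Rotate ``moving`` onto ``reference`` (both centred); returns rotated copy."""
    return moving @ optimal_rotation(reference, moving)


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, check: bool = True, tol: float = 1e-6
) -> float:
    """Full Procrustes distance between two centred, unit-size configurations.

    Root of summed squared coordinate differences after the optimal
    proper rotation of ``b`` onto ``a``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if check:
        for name, c in (("a", a), ("b", b)):
            if np.abs(c.mean(axis=0)).max() > tol:
                raise ValidationError(f"configuration {name} is not centred")
            if abs(np.sqrt(np.sum(c**2)) - 1.0) > tol:
                raise ValidationError(f"configuration {name} does not have unit centroid size")
    rotated = superimpose(a, b)
    return float(np.linalg.norm(a - rotated))


def normalize_config(coords: np.ndarray) -> np.ndarray:
    """Centre a configuration and scale it to unit centroid size."""
    return _centre_and_scale(np.asarray(coords, float))[0]


def pairwise_procrustes_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Full Procrustes distance between two raw configurations.

    Convenience wrapper that centres and unit-scales both inputs first.
    """
    return procrustes_distance(
        normalize_config(coords_a), normalize_config(coords_b), check=False
    )


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalised Procrustes analysis of a landmark sample.

    Parameters
    ----------
    dataset : LandmarkDataset or (n, N, 2) array
        Raw landmark configurations.
    tol : float
        Convergence tolerance on the root-mean-square change of the
        consensus between iterations.
    max_iter : int
        Iteration cap; non-convergence sets ``converged=False`` and
        emits a warning, but results are still returned.
    """
    if isinstance(dataset, LandmarkDataset):
        raw = dataset.coords_array()
        specimen_ids = dataset.specimen_ids
        labels = dataset.labels
        view = dataset.view
    else:
        raw = np.asarray(dataset, float)
        specimen_ids = [f"config_{i}" for i in range(raw.shape[0])]
        labels = [""] * raw.shape[0]
        view = "other"
    if raw.ndim != 3 or raw.shape[2] != 2:
        raise ValidationError(f"expected (n, N, 2) coordinates, got {raw.shape}")
    n = raw.shape[0]
    if n < 2:
        raise ValidationError("GPA needs at least two configurations")

    aligned = np.empty_like(raw)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _centre_and_scale(raw[i])

    consensus = aligned[0].copy()
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = superimpose(consensus, aligned[i])
        mean_shape = aligned.mean(axis=0)
        mean_shape -= mean_shape.mean(axis=0)
        norm = np.sqrt(np.sum(mean_shape**2))
        if norm == 0.0:
            raise DegenerateShapeError("consensus collapsed to a point")
        new_consensus = mean_shape / norm
        history.append(float(np.sum((aligned - new_consensus) ** 2)))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations "
            f"(last consensus change {change:.3e})",
            RuntimeWarning,
        )
    # Final pass so every configuration is optimally rotated onto the
    # returned consensus.
    for i in range(n):
        aligned[i] = superimpose(consensus, aligned[i])

    return AlignedDataset(
        coords=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations_used=iterations,
        converged=converged,
        specimen_ids=list(specimen_ids),
        labels=list(labels),
        view=view,
        objective_history=history,
    )
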