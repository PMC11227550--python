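"""Functional representation of aligned landmark configurations.

A Procrustes-aligned configuration is an ordered sequence of points, so
each specimen can equivalently be viewed as two curves sampled on the
landmark-index continuum: an x-curve and a y-curve over a common grid
on [0, 1].  A sample of specimens then becomes multivariate functional
data with d = 2 elements per view (2V for V views combined), the input
to multivariate functional PCA.

The default representation is the raw grid embedding — values at the
grid points equal the aligned coordinates — with trapezoidal quadrature
weights supplying the L2 inner product.  B-spline least-squares
smoothing is available for noisy inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .landmark_io import ValidationError
from .procrustes import AlignedDataset


class ConfigurationError(ValueError):
    """Raised for invalid smoothing or representation settings."""


@dataclass
class SmoothingSpec:
    """B-spline least-squares smoothing settings.

    ``n_basis`` basis functions of order ``order`` (order = degree + 1;
    4 means cubic) on a clamped uniform knot sequence over [0, 1].
    With ``n_basis`` equal to the grid size the fit interpolates the
    raw values.
    """

    n_basis: int
    order: int = 4


@dataclass
class FunctionalElement:
    """One element (dimension) of a multivariate functional dataset."""

    name: str
    values: np.ndarray  # (n, N_p)
    grid: np.ndarray  # (N_p,) strictly increasing in [0, 1]
    weights: np.ndarray  # (N_p,) quadrature weights summing to 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.grid = np.asarray(self.grid, float)
        self.weights = np.asarray(self.weights, float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.shape[0]:
            raise ValidationError(
                f"element {self.name!r}: values shape {self.values.shape} "
                f"does not match grid length {self.grid.shape[0]}"
            )
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError(f"element {self.name!r}: grid is not strictly increasing")
        if self.grid[0] < -1e-12 or self.grid[-1] > 1 + 1e-12:
            raise ValidationError(f"element {self.name!r}: grid outside [0, 1]")
        if np.any(self.weights < 0):
            raise ValidationError(f"element {self.name!r}: negative quadrature weight")


@dataclass
class FunctionalDataset:
    """n specimens x d elements of discretised curves on common grids."""

    elements: list[FunctionalElement]
    specimen_ids: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValidationError("dataset must contain at least one element")
        n = len(self.specimen_ids)
        for el in self.elements:
            if el.values.shape[0] != n:
                raise ValidationError(
                    f"element {el.name!r} has {el.values.shape[0]} rows, "
                    f"expected {n} specimens"
                )
        if not self.labels:
            self.labels = [""] * n

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def d(self) -> int:
        return len(self.elements)

    @property
    def element_names(self) -> list[str]:
        return [el.name for el in self.elements]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for a strictly increasing grid.

    On a grid spanning [0, 1] the weights sum to the domain length 1.
    """
    grid = np.asarray(grid, float)
    h = np.diff(grid)
    w = np.zeros_like(grid)
    w[:-1] += h / 2
    w[1:] += h / 2
    return w


def inner_product(f: np.ndarray, g: np.ndarray, weights: np.ndarray) -> float:
    """Quadrature L2 inner product of two curves sampled on a common grid."""
    return float(np.sum(np.asarray(f) * np.asarray(g) * np.asarray(weights)))


def _bspline_design(grid: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    k = spec.order - 1  # polynomial degree
    n_basis = spec.n_basis
    if n_basis <= k:
        raise ConfigurationError(
            f"n_basis={n_basis} must exceed the spline degree {k}"
        )
    n_interior = n_basis - k - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(k + 1), interior, np.ones(k + 1)])
    return BSpline.design_matrix(grid, knots, k).toarray()


def _smooth(values: np.ndarray, grid: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    design = _bspline_design(grid, spec)
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return (design @ coef).T


def to_functional(
    aligned: AlignedDataset,
    smoothing: SmoothingSpec | tuple[int, int] | None = None,
    element_prefix: str = "",
    parameterisation: str = "index",
) -> FunctionalDataset:
    """Embed an aligned landmark sample as two-element functional data.

    Parameters
    ----------
    aligned : AlignedDataset
        GPA output; landmark order defines the functional domain.
    smoothing : SmoothingSpec or (n_basis, order) or None
        Optional B-spline least-squares smoothing.  Default None: the
        curves take the aligned coordinates as their grid values (a
        lossless embedding); the data-driven FPCA basis then plays the
        role of a smoother.
    element_prefix : str
        Prepended to element names, e.g. ``"dorsal_"`` -> ``dorsal_x``.
        Defaults to the dataset's view name when that is informative.
    parameterisation : {"index", "arclength"}
        ``index`` maps landmark j to t = (j-1)/(N-1) — digitisation
        order is the only ordering defined for landmark data.
        ``arclength`` uses normalised cumulative chord length along the
        consensus shape instead.
    """
    n_landmarks = aligned.n_landmarks
    if n_landmarks < 4:
        raise ValidationError("need at least 4 landmarks for a functional representation")
    if not np.all(np.isfinite(aligned.coords)):
        raise ValidationError("non-finite aligned coordinates")
    if parameterisation == "index":
        grid = np.linspace(0.0, 1.0, n_landmarks)
    elif parameterisation == "arclength":
        steps = np.linalg.norm(np.diff(aligned.consensus, axis=0), axis=1)
        cumulative = np.concatenate([[0.0], np.cumsum(steps)])
        if cumulative[-1] == 0:
            raise ValidationError("degenerate consensus: zero total chord length")
        grid = cumulative / cumulative[-1]
    else:
        raise ConfigurationError(f"unknown parameterisation {parameterisation!r}")

    if smoothing is not None and not isinstance(smoothing, SmoothingSpec):
        smoothing = SmoothingSpec(*smoothing)
    if smoothing is not None and smoothing.n_basis > n_landmarks:
        raise ConfigurationError(
            f"smoothing basis count {smoothing.n_basis} exceeds the "
            f"number of landmarks {n_landmarks}"
        )

    if not element_prefix and aligned.view not in ("", "other"):
        element_prefix = f"{aligned.view}_"
    weights = trapezoid_weights(grid)
    elements = []
    for axis, axis_name in enumerate(("x", "y")):
        values = aligned.coords[:, :, axis]
        if smoothing is not None:
            values = _smooth(values, grid, smoothing)
        elements.append(
            FunctionalElement(
                name=f"{element_prefix}{axis_name}",
                values=values,
                grid=grid,
                weights=weights,
            )
        )
    return FunctionalDataset(
        elements=elements,
        specimen_ids=list(aligned.specimen_ids),
        labels=list(aligned.labels),
    )


def combine_views(views: list[FunctionalDataset]) -> FunctionalDataset:
    """Concatenate the elements of several views into one multivariate datum.

    Rows are matched by specimen id (the first view's order is kept);
    a specimen present in one view but absent from another is an error.
    """
    if len(views) < 2:
        raise ValidationError("need at least two views to combine")
    ref = views[0]
    ref_ids = ref.specimen_ids
    ref_set = set(ref_ids)
    for v, view in enumerate(views[1:], start=2):
        mismatch = ref_set.symmetric_difference(view.specimen_ids)
        if mismatch:
            raise ValidationError(
                f"view {v}: specimen ids not shared across views: {sorted(mismatch)}"
            )
    elements: list[FunctionalElement] = []
    for view in views:
        order = [view.specimen_ids.index(i) for i in ref_ids]
        for el in view.elements:
            elements.append(
                FunctionalElement(
                    name=el.name,
                    values=el.values[order],
                    grid=el.grid.copy(),
                    weights=el.weights.copy(),
                )
            )
    return FunctionalDataset(
        elements=elements,
        specimen_ids=list(ref_ids),
        labels=list(ref.labels),
    )


def to_long_dataframe(fd: FunctionalDataset):
    """Long-format export: specimen_id, element, t, value."""
    import pandas as pd

    frames = []
    for el in fd.elements:
        n, n_grid = el.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": np.repeat(fd.specimen_ids, n_grid),
                    "element": el.name,
                    "t": np.tile(el.grid, n),
                    "value": el.values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
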