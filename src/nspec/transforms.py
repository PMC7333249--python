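"""Spectral transformation techniques: first-derivative reflectance (FDR)
and continuum removal (CR).

FDR replaces each band with the finite-difference slope of the spectrum,

    FDR(lambda_i) = [R(lambda_{i+1}) - R(lambda_{i-1})] / (2 * dlambda),

which is exactly invariant to additive baselines (the mechanism by which it
suppresses soil/atmospheric background).  Endpoints use one-sided
differences so the grid length is preserved and band indices keep their
wavelengths.

CR divides each spectrum by its upper convex hull (the "continuum line"
connecting the local maxima), normalizing absorption features to (0, 1]
with value exactly 1 at hull vertices; it is invariant to positive
rescaling of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectralDataset
from .exceptions import ConfigurationError, DomainError, NspecError, SizeError

TRANSFORM_KINDS = ("raw", "fdr", "cr")


@dataclass
class ContinuumHull:
    """Upper convex hull of one spectrum.

    ``hull_line`` is the piecewise-linear continuum evaluated on the full
    grid; vertices always include both grid endpoints, and collinear points
    are kept as vertices (their CR value is 1 either way).
    """

    vertex_wavelengths: np.ndarray
    vertex_reflectances: np.ndarray
    hull_line: np.ndarray


def first_derivative(dataset: SpectralDataset) -> SpectralDataset:
    """First-derivative reflectance on an equally spaced grid.

    Interior bands get the central difference over 2*dlambda; the two
    endpoints get one-sided differences over dlambda.
    """
    if dataset.n_bands < 3:
        raise SizeError("first derivative needs at least 3 bands")
    step = dataset.grid_step()
    deriv = np.gradient(dataset.reflectance, step, axis=1, edge_order=1)
    return dataset.with_matrix(deriv, "fdr")


def upper_convex_hull(wavelengths: np.ndarray, values: np.ndarray) -> ContinuumHull:
    """Monotone-chain upper hull of points (wavelength, value), O(n).

    Points already sorted by wavelength.  Collinear points are retained as
    vertices (pop only on strict convexity violations).
    """
    x = np.asarray(wavelengths, dtype=float)
    y = np.asarray(values, dtype=float)
    stack: list[int] = []
    for k in range(x.size):
        while len(stack) >= 2:
            i, j = stack[-2], stack[-1]
            # cross product of (j - i) x (k - i); > 0 means j lies strictly
            # below the chord i->k, so j is not on the upper envelope
            cross = (x[j] - x[i]) * (y[k] - y[i]) - (y[j] - y[i]) * (x[k] - x[i])
            if cross > 0:
                stack.pop()
            else:
                break
        stack.append(k)
    vx, vy = x[stack], y[stack]
    hull_line = np.interp(x, vx, vy)
    return ContinuumHull(vertex_wavelengths=vx, vertex_reflectances=vy, hull_line=hull_line)


def continuum_removal(
    dataset: SpectralDataset,
) -> tuple[SpectralDataset, list[ContinuumHull]]:
    """Continuum-removed spectra and the per-sample hulls.

    CR(lambda) = R(lambda) / hull(lambda), computed over the full analyzed
    range as a single segment.  Requires strictly positive reflectance.
    """
    if dataset.domain_tag != "reflectance":
        raise NspecError("continuum removal expects raw reflectance input")
    if np.any(dataset.reflectance <= 0):
        raise DomainError("continuum removal requires strictly positive reflectance")
    hulls: list[ContinuumHull] = []
    out = np.empty_like(dataset.reflectance)
    for i, row in enumerate(dataset.reflectance):
        hull = upper_convex_hull(dataset.wavelengths, row)
        cr = np.minimum(row / hull.hull_line, 1.0)
        # hull vertices sit on the continuum by construction
        vidx = np.searchsorted(dataset.wavelengths, hull.vertex_wavelengths)
        cr[vidx] = 1.0
        out[i] = cr
        hulls.append(hull)
    return dataset.with_matrix(out, "cr"), hulls


def apply_transform(dataset: SpectralDataset, kind: str) -> SpectralDataset:
    """Dispatch over the three spectral techniques: raw, fdr, cr."""
    if dataset.domain_tag != "reflectance":
        raise NspecError("transforms expect raw reflectance input")
    if kind == "raw":
        return dataset
    if kind == "fdr":
        return first_derivative(dataset)
    if kind == "cr":
        transformed, _ = continuum_removal(dataset)
        return transformed
    raise ConfigurationError(f"unknown transform kind {kind!r}; expected one of {TRANSFORM_KINDS}")
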