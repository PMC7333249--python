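"""Spectral smoothing and wavelength-grid management.

Smoothing uses the Savitzky-Golay filter (local least-squares polynomial);
the study default is a second-order polynomial over a five-band window,
whose interior convolution weights are (-3, 12, 17, 12, -3)/35.  Smoothing
is applied once to raw reflectance, before any transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset
from .exceptions import ConfigurationError, RangeError, SizeError


@dataclass(frozen=True)
class SmoothingSpec:
    """Savitzky-Golay parameters.

    ``edge_policy``:

    - ``"reflect"`` (default): mirror padding; the output keeps every band.
    - ``"shrink"``: only fully windowed interior bands are returned; the
      grid loses ``window - 1`` bands (half at each end).
    """

    window: int = 5
    polyorder: int = 2
    edge_policy: str = "reflect"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ConfigurationError("window must be odd and exceed polyorder")
        if self.polyorder < 0:
            raise ConfigurationError("polyorder must be non-negative")
        if self.edge_policy not in ("reflect", "shrink"):
            raise ConfigurationError(f"unknown edge_policy {self.edge_policy!r}")


def savgol_smooth(dataset: SpectralDataset, spec: SmoothingSpec | None = None) -> SpectralDataset:
    """Smooth each spectrum with a Savitzky-Golay filter.

    Interior bands receive the exact local least-squares polynomial value;
    edges are handled per ``spec.edge_policy``.  The grid must be equally
    spaced and at least ``window`` bands wide.
    """
    spec = spec or SmoothingSpec()
    if spec.window > dataset.n_bands:
        raise SizeError(
            f"window {spec.window} exceeds band count {dataset.n_bands}"
        )
    dataset.grid_step()  # raises GridError on uneven grids
    smoothed = savgol_filter(
        dataset.reflectance, spec.window, spec.polyorder, axis=1, mode="mirror"
    )
    if spec.edge_policy == "shrink":
        half = spec.window // 2
        return SpectralDataset(
            wavelengths=dataset.wavelengths[half:-half].copy(),
            reflectance=np.clip(smoothed[:, half:-half], 0.0, 1.0),
            leaf_n=dataset.leaf_n.copy(),
            sample_ids=list(dataset.sample_ids),
            domain_tag=dataset.domain_tag,
        )
    return dataset.with_matrix(np.clip(smoothed, 0.0, 1.0), dataset.domain_tag)


def crop_resample(
    dataset: SpectralDataset, start: float, stop: float, step: float
) -> SpectralDataset:
    """Restrict the grid to [start, stop] at the given step.

    Values at new grid points are linearly interpolated from the original
    grid; grid points that coincide with original bands pass through
    unchanged.  The result has ``(stop - start)/step + 1`` bands.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    lo, hi = dataset.wavelengths[0], dataset.wavelengths[-1]
    if start < lo - 1e-9 or stop > hi + 1e-9 or start >= stop:
        raise RangeError(
            f"requested range [{start}, {stop}] outside available [{lo}, {hi}]"
        )
    n_steps = (stop - start) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError("step must divide (stop - start)")
    new_wl = start + step * np.arange(int(round(n_steps)) + 1)
    new_matrix = np.vstack(
        [np.interp(new_wl, dataset.wavelengths, row) for row in dataset.reflectance]
    )
    return SpectralDataset(
        wavelengths=new_wl,
        reflectance=new_matrix,
        leaf_n=dataset.leaf_n.copy(),
        sample_ids=list(dataset.sample_ids),
        domain_tag=dataset.domain_tag,
    )
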