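"""Per-wavelength correlation between leaf N and each spectral technique."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .exceptions import DegenerateDataError, RangeError, SizeError

logger = logging.getLogger(__name__)

#: Spectral regions as the source study labels them (its "ultraviolet"
#: 400-420 nm is violet-blue visible light; the label is kept as printed).
#: Boundary bands belong to the lower-wavelength region.
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "ultraviolet": (400.0, 420.0),
    "visible": (421.0, 700.0),
    "near_infrared": (701.0, 950.0),
}


@dataclass
class CorrelationProfile:
    """Band-wise Pearson r between spectra and leaf N."""

    wavelengths: np.ndarray
    r: np.ndarray
    n: int
    technique: str

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths, "r": self.r}).to_csv(
            path, index=False
        )


def wavelength_correlations(dataset: SpectralDataset) -> CorrelationProfile:
    """Pearson r between each band and leaf N.

    Constant bands yield r = 0 (with a logged warning); a constant response
    is an error because no band-wise correlation is defined.
    """
    if dataset.n_samples < 3:
        raise SizeError("correlation needs at least 3 samples")
    y = dataset.leaf_n
    if np.ptp(y) == 0:
        raise DegenerateDataError("leaf_n is constant; correlations undefined")
    X = dataset.reflectance
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    if constant.any():
        logger.warning(
            "%d constant band(s) in correlation analysis; their r set to 0",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    return CorrelationProfile(
        wavelengths=dataset.wavelengths.copy(),
        r=r,
        n=dataset.n_samples,
        technique=dataset.domain_tag if dataset.domain_tag != "reflectance" else "raw",
    )


def region_mean_r(
    profile: CorrelationProfile,
    regions: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Arithmetic mean of r over the bands of each closed nm interval."""
    regions = regions or DEFAULT_REGIONS
    out: dict[str, float] = {}
    for name, (lo, hi) in regions.items():
        mask = (profile.wavelengths >= lo) & (profile.wavelengths <= hi)
        if not mask.any():
            raise RangeError(f"region {name!r} [{lo}, {hi}] contains no bands")
        out[name] = float(profile.r[mask].mean())
    return out
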