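"""VIP scores and effective-wavelength selection from a fitted PLS model.

The variable importance in projection of band j over A latent variables is

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a ),

where SSY_a = q_a^2 * (t_a' t_a) is the response variance explained by
component a, w_a the loading-weight vector and p the band count.  The
normalization makes the squared scores average to 1 (sum VIP^2 = p), which
is why 1.0 is the conventional threshold; with many contiguous informative
bands a stricter threshold (2.0 in the emulated study) isolates discrete
effective wavelengths.  Bands above threshold are grouped into contiguous
runs and each run contributes its VIP-argmax band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, NspecError
from .regression import FittedModel


@dataclass
class VIPProfile:
    """Per-band VIP scores with the selection threshold applied."""

    wavelengths: np.ndarray
    vip: np.ndarray
    threshold: float
    selected: list[tuple[float, float]]

    def to_csv(self, path) -> None:
        sel_wl = {w for w, _ in self.selected}
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "vip": self.vip,
                "selected_flag": [int(w in sel_wl) for w in self.wavelengths],
            }
        ).to_csv(path, index=False)


def vip_scores(
    model: FittedModel, wavelengths: np.ndarray, threshold: float = 1.0
) -> VIPProfile:
    """VIP profile of a fitted PLS model over its selected components."""
    if model.method != "PLS" or model.loading_weights is None:
        raise NspecError("VIP scores require a fitted PLS model")
    W = model.loading_weights
    q = np.asarray(model.y_loadings, dtype=float)
    T = model.x_scores
    p, A = W.shape
    ssy = q**2 * (T**2).sum(axis=0)
    total = ssy.sum()
    if total <= 0:
        raise DegenerateDataError("PLS model explains no response variance")
    norms = np.linalg.norm(W, axis=0)
    vip = np.sqrt(p * ((W / norms) ** 2) @ (ssy / total))
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != p:
        raise NspecError("wavelength grid does not match the model band count")
    profile = VIPProfile(
        wavelengths=wavelengths, vip=vip, threshold=threshold, selected=[]
    )
    profile.selected = select_effective_wavelengths(profile, threshold)
    return profile


def select_effective_wavelengths(
    profile: VIPProfile, threshold: float
) -> list[tuple[float, float]]:
    """One effective wavelength per contiguous above-threshold run.

    Bands with VIP >= threshold are grouped into maximal contiguous runs
    along the grid; each run contributes the band with the highest VIP.
    An empty selection is valid (threshold above max VIP).
    """
    if threshold <= 0:
        raise NspecError("threshold must be positive")
    mask = profile.vip >= threshold
    selected: list[tuple[float, float]] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            run = slice(i, j + 1)
            best = i + int(np.argmax(profile.vip[run]))
            selected.append((float(profile.wavelengths[best]), float(profile.vip[best])))
            i = j + 1
        else:
            i += 1
    return sorted(selected)


def loading_weight_profile(model: FittedModel, component: int) -> np.ndarray:
    """Unit-norm loading-weight column of one latent variable (1-based)."""
    if model.method != "PLS" or model.loading_weights is None:
        raise NspecError("loading weights require a fitted PLS model")
    A = model.loading_weights.shape[1]
    if not 1 <= component <= A:
        raise IndexError(f"component {component} out of range 1..{A}")
    return model.loading_weights[:, component - 1].copy()
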