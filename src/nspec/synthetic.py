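"""Synthetic winter-wheat canopy spectra paired with leaf N concentration.

Field campaigns of this kind are rarely deposited, so the package ships a
mechanistic (phenomenological, not radiative-transfer) generator that
reproduces the statistical structure such studies report:

- leaf N spanning roughly 1--6 % with a truncated-normal distribution;
- visible reflectance (400--700 nm) *decreasing* with leaf N, because
  chlorophyll tracks N and absorbs blue (~450 nm) and red (~670 nm) light,
  leaving the familiar green peak near 550 nm;
- a red-edge logistic transition near 700--730 nm whose inflection shifts
  to longer wavelengths as N (chlorophyll) increases;
- a near-infrared plateau (750--950 nm) *increasing* with N as a proxy for
  canopy structure (biomass, leaf area index);
- narrow N-modulated features planted at configurable "informative
  centers" so that wavelength-selection methods have a known ground truth
  to recover;
- per-scan white instrument noise averaged over ``scans_per_sample`` scans
  and a smooth per-sample additive baseline drift (soil/illumination
  background) that a derivative transform should suppress.

With zero noise and drift the construction is monotone in leaf N at every
visible band (non-increasing) and every NIR band (non-decreasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataset import SpectralDataset
from .exceptions import ConfigurationError, NspecError, SizeError

#: Effective wavelengths (nm) that drive the planted narrow features.
DEFAULT_INFORMATIVE_CENTERS = (525.0, 573.0, 710.0, 780.0, 875.0, 924.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the pooled field campaign this package emulates:
    315 samples, leaf N with mean 3.80 %, SD 1.24 % truncated to
    [1.06, 6.16] %, a 400--950 nm grid at 1 nm (551 bands), 60 scans
    averaged per sample.
    """

    n_samples: int = 315
    n_mean: float = 3.80
    n_sd: float = 1.24
    n_min: float = 1.06
    n_max: float = 6.16
    wavelength_start: float = 400.0
    wavelength_stop: float = 950.0
    wavelength_step: float = 1.0
    informative_centers: tuple[float, ...] = DEFAULT_INFORMATIVE_CENTERS
    noise_sd: float = 0.004
    drift_amplitude: float = 0.02
    structure_jitter_sd: float = 0.30
    scans_per_sample: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be non-negative")
        if self.n_sd < 0:
            raise ConfigurationError("n_sd must be non-negative")
        if self.n_min >= self.n_max:
            raise ConfigurationError(
                f"infeasible truncation: n_min={self.n_min} >= n_max={self.n_max}"
            )
        if not (self.n_min < self.n_mean < self.n_max):
            raise ConfigurationError("require n_min < n_mean < n_max")
        if self.wavelength_step <= 0:
            raise ConfigurationError("wavelength_step must be positive")
        span = self.wavelength_stop - self.wavelength_start
        if span <= 0:
            raise ConfigurationError("wavelength_stop must exceed wavelength_start")
        n_steps = span / self.wavelength_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError("wavelength_step must divide the grid span")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.structure_jitter_sd < 0:
            raise ConfigurationError(
                "noise_sd, drift_amplitude and structure_jitter_sd must be >= 0"
            )
        if self.scans_per_sample < 1:
            raise ConfigurationError("scans_per_sample must be >= 1")
        self.informative_centers = tuple(float(c) for c in self.informative_centers)

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start) / self.wavelength_step))
        return self.wavelength_start + self.wavelength_step * np.arange(n + 1)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stochastic component
    return np.random.default_rng([int(config.seed), stream])


def simulate_leaf_n(config: SimulationConfig) -> np.ndarray:
    """Draw leaf N concentrations (%) from a truncated normal.

    Rejection sampling of N(n_mean, n_sd) restricted to [n_min, n_max]; the
    simplest distribution consistent with the four summary statistics
    (mean, SD, min, max) such campaigns report.  ``n_sd == 0`` degenerates
    to a constant at ``n_mean``.
    """
    if config.n_sd == 0.0:
        return np.full(config.n_samples, config.n_mean)
    rng = _rng(config, 0)
    out = np.empty(config.n_samples)
    filled = 0
    while filled < config.n_samples:
        batch = rng.normal(config.n_mean, config.n_sd, size=max(2 * config.n_samples, 64))
        keep = batch[(batch >= config.n_min) & (batch <= config.n_max)]
        take = min(keep.size, config.n_samples - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# -- the mechanistic spectrum ---------------------------------------------

_VIS_BASE = 0.15           # visible baseline reflectance
_ABS_DEPTH0 = 0.020        # chlorophyll absorption depth at N = 0
_ABS_DEPTH_SLOPE = 0.012   # absorption deepening per % leaf N
_BLUE_CENTER, _BLUE_SIGMA = 450.0, 60.0
_RED_CENTER, _RED_SIGMA = 670.0, 45.0
_NIR_BASE, _NIR_GAIN = 0.34, 0.06        # NIR plateau level vs normalized N
_RED_EDGE_BASE, _RED_EDGE_SHIFT = 708.0, 4.0   # inflection nm vs normalized N
_RED_EDGE_WIDTH = 8.0
_FEATURE_AMPLITUDE = 0.05
_FEATURE_SIGMA = 5.0


def _normalized_n(leaf_n: np.ndarray, config: SimulationConfig) -> np.ndarray:
    return (leaf_n - config.n_min) / (config.n_max - config.n_min)


def clean_spectra(leaf_n: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Noise- and drift-free spectra for the given leaf N values.

    Exposed separately so tests can verify the monotone construction and
    measure noise residuals against the deterministic component.
    """
    leaf_n = np.asarray(leaf_n, dtype=float)[:, None]
    wl = config.wavelength_grid()[None, :]
    u = _normalized_n(leaf_n[:, 0], config)[:, None]

    depth = _ABS_DEPTH0 + _ABS_DEPTH_SLOPE * leaf_n
    absorption = 0.8 * np.exp(-((wl - _BLUE_CENTER) ** 2) / (2 * _BLUE_SIGMA**2))
    absorption = absorption + np.exp(-((wl - _RED_CENTER) ** 2) / (2 * _RED_SIGMA**2))
    visible = _VIS_BASE - depth * absorption

    plateau = _NIR_BASE + _NIR_GAIN * u
    inflection = _RED_EDGE_BASE + _RED_EDGE_SHIFT * u
    s = 1.0 / (1.0 + np.exp(-(wl - inflection) / _RED_EDGE_WIDTH))
    base = visible + (plateau - visible) * s

    feat = np.zeros_like(base)
    for center in config.informative_centers:
        sign = -1.0 if center <= 700.0 else 1.0
        feat += sign * _FEATURE_AMPLITUDE * u * np.exp(
            -((wl - center) ** 2) / (2 * _FEATURE_SIGMA**2)
        )
    return np.clip(base + feat, 1e-3, 1.0 - 1e-3)


def simulate_spectra(leaf_n: np.ndarray, config: SimulationConfig) -> SpectralDataset:
    """Generate a :class:`SpectralDataset` for the given leaf N vector.

    Adds, on top of :func:`clean_spectra`:

    - per-sample structural scatter: the spectrum is evaluated at a
      jittered N proxy (``leaf_n + N(0, structure_jitter_sd)``), modelling
      the imperfect coupling between leaf N and the optically expressed
      canopy state (chlorophyll, biomass); this floor is irreducible by
      any calibration model and keeps validation statistics in the range
      field campaigns report;

    - a per-sample smooth additive background drift: a random low-frequency
      cosine/sine series (12 harmonics over the grid, amplitudes falling as
      1/j) normalized so its per-band SD equals ``drift_amplitude``.  The
      series is smooth, so a derivative transform suppresses it, but it is
      high-dimensional enough that raw-domain models cannot simply project
      it out — the behaviour of real soil/illumination backgrounds;
    - white instrument noise of SD ``noise_sd`` per scan; averaging
      ``scans_per_sample`` i.i.d. scans is realized as a single draw with
      SD ``noise_sd / sqrt(scans_per_sample)`` (identical in distribution,
      and with a common seed the underlying standard-normal field is
      shared across different scan counts).
    """
    leaf_n = np.asarray(leaf_n, dtype=float)
    if not np.all(np.isfinite(leaf_n)) or np.any(leaf_n <= 0):
        raise NspecError("leaf_n must be finite and positive")
    wl = config.wavelength_grid()
    n = leaf_n.size

    # biological/structural scatter: the canopy expresses its N status
    # imperfectly, so spectra respond to a jittered N proxy.  This puts an
    # irreducible floor under any calibration, as field data do.
    jitter_rng = _rng(config, 3)
    n_expressed = leaf_n + config.structure_jitter_sd * jitter_rng.standard_normal(n)
    clean = clean_spectra(n_expressed, config)
    drift_rng = _rng(config, 1)
    n_harmonics = 60
    u = (wl - wl[0]) / (wl[-1] - wl[0])  # in [0, 1]
    j = np.arange(1, n_harmonics + 1)
    basis = np.concatenate(
        [np.cos(np.pi * np.outer(j, u)) / j[:, None],
         np.sin(np.pi * np.outer(j, u)) / j[:, None]],
        axis=0,
    )  # (2J, p), harmonic amplitudes falling as 1/j
    coeffs = drift_rng.standard_normal(size=(n, 2 * n_harmonics))
    # per-band drift SD = drift_amplitude (the 1/j series has SD ~1.12)
    norm = np.sqrt(np.mean((basis**2).sum(axis=0)))
    drift = config.drift_amplitude * (coeffs @ basis) / norm

    noise_rng = _rng(config, 2)
    standard = noise_rng.standard_normal(size=(n, wl.size))
    noise = (config.noise_sd / np.sqrt(config.scans_per_sample)) * standard

    reflectance = np.clip(clean + drift + noise, 1e-3, 1.0 - 1e-3)
    return SpectralDataset(
        wavelengths=wl,
        reflectance=reflectance,
        leaf_n=leaf_n.copy(),
        domain_tag="reflectance",
    )


def simulate_dataset(config: SimulationConfig) -> SpectralDataset:
    """Leaf N draw + spectra in one call (the generator's main entry point)."""
    return simulate_spectra(simulate_leaf_n(config), config)


def split_dataset(
    dataset: SpectralDataset, n_cal: int, n_val: int, seed: int
) -> tuple[SpectralDataset, SpectralDataset]:
    """Random disjoint calibration/validation split, reproducible under seed."""
    if n_cal < 0 or n_val < 0:
        raise SizeError("split sizes must be non-negative")
    if n_cal + n_val > dataset.n_samples:
        raise SizeError(
            f"requested {n_cal}+{n_val} samples but only {dataset.n_samples} available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_samples)
    cal_idx = np.sort(perm[:n_cal])
    val_idx = np.sort(perm[n_cal : n_cal + n_val])
    return dataset.take(cal_idx), dataset.take(val_idx)


def truncated_normal_moments(
    mean: float, sd: float, lo: float, hi: float, n_grid: int = 20001
) -> tuple[float, float]:
    """Mean and SD of N(mean, sd) truncated to [lo, hi], by quadrature.

    Provided for verification of :func:`simulate_leaf_n`; uses trapezoidal
    integration of the truncated density on a fine grid.
    """
    x = np.linspace(lo, hi, n_grid)
    dens = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    z = np.trapezoid(dens, x)
    m1 = np.trapezoid(x * dens, x) / z
    m2 = np.trapezoid(x**2 * dens, x) / z
    return float(m1), float(np.sqrt(m2 - m1**2))
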