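"""Spectral dataset container and its CSV dialect.

A :class:`SpectralDataset` holds a wavelength grid (nm), a samples x bands
matrix, and the per-sample leaf nitrogen concentration (%, the response
used throughout).  The matrix may live in one of three domains, recorded in
``domain_tag``:

- ``"reflectance"`` -- raw (or smoothed) canopy reflectance in [0, 1];
- ``"fdr"``         -- first-derivative reflectance (signed, per nm);
- ``"cr"``          -- continuum-removed reflectance in (0, 1].

CSV layout: one optional comment line ``# domain_tag: <tag>`` (written for
transformed data), then a header ``sample_id,leaf_n_pct,<wl>,...`` with one
column per integer wavelength in nm, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import GridError, NspecError, SizeError

DOMAIN_TAGS = ("reflectance", "fdr", "cr")


@dataclass
class SpectralDataset:
    """Paired canopy spectra and leaf N concentrations.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, shape ``(p,)``.
    reflectance
        Spectral matrix, shape ``(n, p)``; values interpreted per ``domain_tag``.
    leaf_n
        Leaf N concentration in %, shape ``(n,)``.
    sample_ids
        One label per sample; generated as ``s0001, ...`` when omitted.
    domain_tag
        One of ``reflectance``, ``fdr``, ``cr``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    leaf_n: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    domain_tag: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.leaf_n = np.asarray(self.leaf_n, dtype=float)
        if self.domain_tag not in DOMAIN_TAGS:
            raise NspecError(f"unknown domain_tag {self.domain_tag!r}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise GridError("wavelengths must be a non-empty 1-D vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise GridError("wavelengths must be strictly increasing")
        n, p = self.reflectance.shape
        if p != self.wavelengths.size:
            raise SizeError(
                f"reflectance has {p} bands but the grid has {self.wavelengths.size}"
            )
        if self.leaf_n.shape != (n,):
            raise SizeError(
                f"leaf_n has length {self.leaf_n.size}, expected {n} (one per sample)"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise NspecError("reflectance contains non-finite values")
        if self.domain_tag == "reflectance":
            if self.reflectance.size and (
                self.reflectance.min() < 0.0 or self.reflectance.max() > 1.0
            ):
                raise NspecError("reflectance values must lie in [0, 1]")
        elif self.domain_tag == "cr":
            if self.reflectance.size and (
                self.reflectance.min() <= 0.0 or self.reflectance.max() > 1.0
            ):
                raise NspecError("continuum-removed values must lie in (0, 1]")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise SizeError("sample_ids length does not match the sample count")
        self.sample_ids = [str(s) for s in self.sample_ids]

    # -- basic protocol ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def grid_step(self) -> float:
        """Return the common grid increment, or raise if the grid is uneven."""
        steps = np.diff(self.wavelengths)
        if steps.size == 0:
            raise GridError("grid has a single band; no increment defined")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise GridError("wavelength grid is not equally spaced")
        return float(steps[0])

    def take(self, indices: Sequence[int]) -> "SpectralDataset":
        """Row subset (new arrays, order given by ``indices``)."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[idx].copy(),
            leaf_n=self.leaf_n[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            domain_tag=self.domain_tag,
        )

    def with_matrix(self, matrix: np.ndarray, domain_tag: str) -> "SpectralDataset":
        """Same samples/grid, new spectral matrix in a (possibly) new domain."""
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            reflectance=np.asarray(matrix, dtype=float),
            leaf_n=self.leaf_n.copy(),
            sample_ids=list(self.sample_ids),
            domain_tag=domain_tag,
        )

    # -- CSV dialect -------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = {"sample_id": self.sample_ids, "leaf_n_pct": self.leaf_n}
        frame = pd.DataFrame(cols)
        wl_names = [_format_wavelength(w) for w in self.wavelengths]
        frame = pd.concat(
            [frame, pd.DataFrame(self.reflectance, columns=wl_names)], axis=1
        )
        with path.open("w", encoding="utf-8", newline="") as fh:
            if self.domain_tag != "reflectance":
                fh.write(f"# domain_tag: {self.domain_tag}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            first = fh.readline()
            tag = "reflectance"
            if first.startswith("#"):
                if "domain_tag:" in first:
                    tag = first.split("domain_tag:", 1)[1].strip()
            else:
                fh.seek(0)
            frame = pd.read_csv(fh)
        required = {"sample_id", "leaf_n_pct"}
        if not required.issubset(frame.columns):
            raise NspecError(f"CSV must contain columns {sorted(required)}")
        wl_cols = [c for c in frame.columns if c not in required]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(
            wavelengths=wavelengths,
            reflectance=frame[wl_cols].to_numpy(dtype=float),
            leaf_n=frame["leaf_n_pct"].to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame["sample_id"]],
            domain_tag=tag,
        )


def _format_wavelength(w: float) -> str:
    return str(int(round(w))) if abs(w - round(w)) < 1e-9 else repr(float(w))
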