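"""Sampled spectral functions and integration primitives.

A :class:`Spectrum` is a tabulated wavelength -> value function on a strictly
increasing nanometre grid.  Three kinds are distinguished because their
invariants differ: radiances and sensitivities are nonnegative, transmittances
additionally live in [0, 1].  Resampling is linear interpolation with zero
outside the tabulated support, which makes products and integrals of spectra
tabulated on different instruments' grids well defined.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "DEFAULT_GRID",
    "load_spectrum_csv",
    "common_grid",
]

#: Canonical analysis grid: 390-780 nm at 1 nm.
DEFAULT_GRID = np.arange(390.0, 781.0)

_KINDS = ("radiance", "transmittance", "sensitivity")


class SpectrumError(ValueError):
    """Raised for invalid spectral data or incompatible supports."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    values
        Per-wavelength magnitude; units depend on ``kind`` (W·sr⁻¹·m⁻²·nm⁻¹
        for radiance, dimensionless otherwise).
    kind
        One of ``radiance``, ``transmittance``, ``sensitivity``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "radiance"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if self.kind not in _KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        # tiny negative values can arise from interpolation of matrix-derived
        # sensitivities; clip them rather than reject
        tiny = vals < 0
        if np.any(tiny):
            if vals[tiny].min() < -1e-9 * max(1.0, vals.max()):
                raise SpectrumError(f"{self.kind} values must be nonnegative")
            vals = np.where(tiny, 0.0, vals)
        if self.kind == "transmittance" and vals.max() > 1.0 + 1e-9:
            raise SpectrumError("transmittance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    # ------------------------------------------------------------------ basics
    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid``; zero outside the support."""
        grid = np.asarray(grid, dtype=float)
        vals = np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)
        return Spectrum(grid, vals, self.kind, self.name)

    def __call__(self, wavelength: float | np.ndarray) -> float | np.ndarray:
        return np.interp(wavelength, self.wavelengths, self.values, left=0.0, right=0.0)

    def scaled(self, factor: float) -> "Spectrum":
        if self.kind == "transmittance":
            raise SpectrumError("scaling a transmittance is not meaningful")
        return Spectrum(self.wavelengths, self.values * factor, self.kind, self.name)

    def __mul__(self, factor: float) -> "Spectrum":
        return self.scaled(float(factor))

    __rmul__ = __mul__

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if other.kind != self.kind:
            raise SpectrumError("cannot add spectra of different kinds")
        grid = common_grid(self, other)
        return Spectrum(grid, self.resample(grid).values + other.resample(grid).values, self.kind)

    def filtered_by(self, transmittance: "Spectrum") -> "Spectrum":
        """Pointwise product with a transmittance spectrum."""
        if transmittance.kind != "transmittance":
            raise SpectrumError("filter must be a transmittance spectrum")
        grid = common_grid(self, transmittance)
        vals = self.resample(grid).values * transmittance.resample(grid).values
        return Spectrum(grid, vals, self.kind, self.name)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def common_grid(*spectra: Spectrum, step: float = 1.0) -> np.ndarray:
    """1-nm grid spanning the overlap of the spectra's supports.

    Raises on empty overlap: integrating two spectra that never coexist in
    wavelength is always a caller error.
    """
    lo = max(s.support[0] for s in spectra)
    hi = min(s.support[1] for s in spectra)
    if hi <= lo:
        raise SpectrumError("spectral supports do not overlap")
    return np.arange(lo, hi + 0.5 * step, step)


def load_spectrum_csv(path: str | os.PathLike, kind: str = "radiance") -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV with a one-line header."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise SpectrumError(f"{path}: expected two columns wavelength_nm,value")
    return Spectrum(data[:, 0], data[:, 1], kind, name=str(path))
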