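"""Packaged standard observer data and cone-fundamental construction.

The package ships three small standard tables as CSV:

* CIE 1931 2° colour-matching functions at 5 nm,
* the Judd (1951) short-wavelength revision of the photopic luminosity
  function V(λ) at 10 nm (identical to CIE ȳ above 460 nm),
* the relative spectral power distribution of CIE Illuminant C at 10 nm.

Cone fundamentals are built from these by the Smith–Pokorny partition of the
Judd-modified luminosity function::

    L(λ) =  0.15514·x̄(λ) + 0.54312·ȳ′(λ) − 0.03286·z̄(λ)
    M(λ) = −0.15514·x̄(λ) + 0.45684·ȳ′(λ) + 0.03286·z̄(λ)
    S(λ) =  0.01608·z̄(λ)

so that L(λ) + M(λ) = ȳ′(λ) = V′(λ) exactly: summed L and M absorptions of a
stimulus equal its (normalised) luminance.  The S scale 0.01608 is the
published constant that sets max_λ S/(L+M) = 1, completing the conventional
MacLeod-Boynton scaling.  x̄ and z̄ are taken from the CIE 1931 set; the full
Judd–Vos revision differs from this only below ~410 nm, which is negligible
for the broadband lights handled here.

Two normalisations of the same family are exposed: ``mb_scaled`` for the
chromaticity/task space, and ``peak_one`` (each curve rescaled to peak 1) for
the cone-gain analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .spectra import Spectrum

__all__ = [
    "ConeFundamentalSet",
    "cie1931_cmfs",
    "judd_vlambda",
    "illuminant_c",
    "task_fundamentals",
    "gain_fundamentals",
]

# Smith-Pokorny partition of Judd luminance into L and M, and the S scale
# that puts max S/(L+M) at 1.
_LM_WEIGHTS = ((0.15514, 0.54312, -0.03286), (-0.15514, 0.45684, 0.03286))
_S_SCALE = 0.01608

_GRID = np.arange(380.0, 781.0)  # native 1-nm grid of the packaged tables


def _table(name: str) -> np.ndarray:
    with resources.files("chromadapt.data").joinpath(name).open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


@dataclass(frozen=True)
class ConeFundamentalSet:
    """L, M, S spectral sensitivities sharing one wavelength grid."""

    L: Spectrum
    M: Spectrum
    S: Spectrum
    normalization: str  # "mb_scaled" | "peak_one"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.normalization not in ("mb_scaled", "peak_one"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not (
            np.array_equal(self.L.wavelengths, self.M.wavelengths)
            and np.array_equal(self.L.wavelengths, self.S.wavelengths)
        ):
            raise ValueError("cone fundamentals must share one wavelength grid")
        if self.normalization == "peak_one":
            for curve in (self.L, self.M, self.S):
                if abs(curve.values.max() - 1.0) > 1e-9:
                    raise ValueError("peak_one fundamentals must peak at exactly 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.L.wavelengths


@lru_cache(maxsize=None)
def cie1931_cmfs() -> tuple[Spectrum, Spectrum, Spectrum]:
    """CIE 1931 2° colour-matching functions x̄, ȳ, z̄ on a 1-nm grid."""
    raw = _table("cie_1931_2deg_cmf_5nm.csv")
    out = []
    for col, label in zip(range(1, 4), ("xbar", "ybar", "zbar")):
        vals = np.interp(_GRID, raw[:, 0], raw[:, col])
        out.append(Spectrum(_GRID, vals, "sensitivity", name=label))
    return tuple(out)


@lru_cache(maxsize=None)
def judd_vlambda() -> Spectrum:
    """Judd-modified photopic luminosity function V′(λ), 1-nm grid.

    CIE 1931 ȳ with the Judd (1951) short-wavelength values spliced in below
    460 nm (linearly interpolated between the 10-nm table points).
    """
    _, ybar, _ = cie1931_cmfs()
    judd = _table("judd1951_vlambda_shortwave_10nm.csv")
    vals = ybar.values.copy()
    short = _GRID <= judd[-1, 0]
    vals[short] = np.interp(_GRID[short], judd[:, 0], judd[:, 1])
    return Spectrum(_GRID, vals, "sensitivity", name="V_judd")


@lru_cache(maxsize=None)
def illuminant_c() -> Spectrum:
    """Relative spectral power distribution of CIE Illuminant C (1-nm grid)."""
    raw = _table("illuminant_c_10nm.csv")
    vals = np.interp(_GRID, raw[:, 0], raw[:, 1])
    return Spectrum(_GRID, vals, "radiance", name="illuminant_C")


def _raw_lms() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xbar, _, zbar = cie1931_cmfs()
    yj = judd_vlambda().values
    x, z = xbar.values, zbar.values
    (a, b, c), (d, e, f) = _LM_WEIGHTS
    # common renormalisation so L + M = V' exactly (published row sums give
    # b + e = 0.99996); a common factor on L and M leaves rmb unchanged
    norm = b + e
    L = (a * x + b * yj + c * z) / norm
    M = (d * x + e * yj + f * z) / norm
    S = _S_SCALE * z
    return L, M, S


@lru_cache(maxsize=None)
def task_fundamentals() -> ConeFundamentalSet:
    """The MacLeod-Boynton-scaled set used to define the stimulus space.

    L + M equals the Judd-modified V(λ) (peak 1), so chromaticity and
    luminance computations share one normalisation.
    """
    L, M, S = _raw_lms()
    return ConeFundamentalSet(
        Spectrum(_GRID, L, "sensitivity", "L_mb"),
        Spectrum(_GRID, M, "sensitivity", "M_mb"),
        Spectrum(_GRID, S, "sensitivity", "S_mb"),
        normalization="mb_scaled",
        provenance="Smith-Pokorny partition of Judd-modified V(lambda)",
    )


@lru_cache(maxsize=None)
def gain_fundamentals() -> ConeFundamentalSet:
    """The same family with every curve rescaled to peak 1 (gain analysis)."""
    L, M, S = _raw_lms()
    return ConeFundamentalSet(
        Spectrum(_GRID, L / L.max(), "sensitivity", "L_peak1"),
        Spectrum(_GRID, M / M.max(), "sensitivity", "M_peak1"),
        Spectrum(_GRID, S / S.max(), "sensitivity", "S_peak1"),
        normalization="peak_one",
        provenance="Smith-Pokorny shapes, peaks scaled to 1",
    )
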