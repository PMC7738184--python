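"""Monitor and red-filter models; rendering hue settings to physical spectra.

The monitor is three gun spectra at full drive plus per-gun gamma (1.0 for a
linearised display).  The packaged default monitor uses Gaussian gun spectra
(CRT-like peaks near 450/530/610 nm) scaled so that full white is 100 cd/m²;
every downstream computation is parameterised by whatever spectra are
supplied, so measured gun tables drop in via the same CSV format.

The red glasses are a logistic transmittance edge.  The default parameters
satisfy the published characterisation of the physical glasses: transmittance
above 0.90 beyond 620 nm and below 0.10 under 550 nm.

Rendering inverts the colour pipeline: because L + M absorptions equal
(normalised) luminance under the task fundamentals, a target (hue angle,
radius, luminance) fixes the absorption triple linearly, and the gun drives
solve a single 3×3 system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import colorspace as cs
from .fundamentals import ConeFundamentalSet, cie1931_cmfs, task_fundamentals
from .spectra import DEFAULT_GRID, Spectrum

__all__ = [
    "MonitorModel",
    "FilterModel",
    "RGBTriple",
    "GamutError",
    "default_monitor",
    "synth_red_glasses",
    "rgb_to_spectrum",
    "apply_filter",
    "render_setting",
    "monitor_gamut",
    "polygon_area",
    "polygon_centroid",
]


class GamutError(ValueError):
    """A chromaticity/luminance target is unreachable by the monitor."""


class RGBTriple(NamedTuple):
    """Linear gun drives in [0, 1]."""

    r: float
    g: float
    b: float


@dataclass(frozen=True)
class MonitorModel:
    gun_spectra: tuple[Spectrum, Spectrum, Spectrum]
    gamma: float = 1.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def max_luminance(self) -> float:
        """Luminance of full white (all guns at drive 1), cd/m²."""
        return sum(cs.luminance(g) for g in self.gun_spectra)


@dataclass(frozen=True)
class FilterModel:
    transmittance: Spectrum
    label: str = ""

    def __post_init__(self) -> None:
        if self.transmittance.kind != "transmittance":
            raise ValueError("filter spectrum must have kind='transmittance'")


def default_monitor(
    peaks: Sequence[float] = (610.0, 530.0, 450.0),
    widths: Sequence[float] = (28.0, 33.0, 30.0),
    white_luminance: float = 100.0,
    gamma: float = 1.0,
) -> MonitorModel:
    """Synthetic CRT-like monitor with Gaussian gun spectra.

    Gun radiances are scaled jointly so that full white reaches
    ``white_luminance`` and individually so the white point sits at the
    Illuminant C chromaticity (the display's nominal white), which keeps the
    whole task hue circle comfortably inside the gamut at 51 cd/m².
    """
    guns = [
        Spectrum(DEFAULT_GRID, np.exp(-0.5 * ((DEFAULT_GRID - p) / w) ** 2), "radiance", n)
        for p, w, n in zip(peaks, widths, ("red_gun", "green_gun", "blue_gun"))
    ]
    # balance guns so that (1,1,1) renders the Illuminant C chromaticity
    fund = task_fundamentals()
    white = cs.scale_mb(cs.MBChromaticity(cs.WHITE_RMB, cs.WHITE_BMB))
    A = _gun_matrix(tuple(guns), fund)
    target = _absorption_target(white, 1.0)
    w = np.linalg.solve(A, target)
    if np.any(w <= 0):
        raise GamutError("gun primaries cannot produce the nominal white")
    guns = [g * float(wi) for g, wi in zip(guns, w)]
    scale = white_luminance / sum(cs.luminance(g) for g in guns)
    guns = [g * scale for g in guns]
    return MonitorModel(tuple(guns), gamma=gamma, name="synthetic_crt")


def synth_red_glasses(
    lambda0: float = 585.0,
    width: float = 8.0,
    floor: float = 0.02,
    ceiling: float = 0.95,
) -> FilterModel:
    """Parametric logistic stand-in for the measured red-glasses curve.

    T(λ) = floor + (ceiling − floor) / (1 + exp(−(λ − lambda0)/width)).
    Parameters must respect the published bounds of the physical glasses
    (T < 0.10 below 550 nm, T > 0.90 above 620 nm) or a ValueError is raised.
    """
    if not (0.0 <= floor < ceiling <= 1.0):
        raise ValueError("need 0 <= floor < ceiling <= 1")
    if width <= 0:
        raise ValueError("width must be positive")
    vals = floor + (ceiling - floor) / (1.0 + np.exp(-(DEFAULT_GRID - lambda0) / width))
    t = Spectrum(DEFAULT_GRID, vals, "transmittance", "synthetic_red_glasses")
    if np.any(t.values[DEFAULT_GRID <= 550.0] >= 0.10):
        raise ValueError("filter violates the short-wavelength bound (T < 0.10 below 550 nm)")
    if np.any(t.values[DEFAULT_GRID >= 620.0] <= 0.90):
        raise ValueError("filter violates the long-wavelength bound (T > 0.90 above 620 nm)")
    return FilterModel(t, label="synthetic red glasses")


def rgb_to_spectrum(rgb: RGBTriple, mon: MonitorModel) -> Spectrum:
    """Physical spectrum emitted for linear gun drives in [0, 1]."""
    arr = np.asarray(rgb, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
        raise ValueError(f"gun drives {tuple(arr)} outside [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    grid = mon.gun_spectra[0].wavelengths
    vals = sum(
        (d ** mon.gamma) * g.resample(grid).values
        for d, g in zip(arr, mon.gun_spectra)
    )
    return Spectrum(grid, vals, "radiance")


def apply_filter(spec: Spectrum, filt: FilterModel) -> Spectrum:
    """Spectrum after passing through the filter (pointwise product)."""
    return spec.filtered_by(filt.transmittance)


def _gun_matrix(guns: tuple[Spectrum, ...], fund: ConeFundamentalSet) -> np.ndarray:
    """Columns are the LMS absorptions of each gun at full (linear) drive."""
    return np.column_stack([np.asarray(cs.cone_absorptions(g, fund)) for g in guns])


def _absorption_target(p: cs.ScaledMB, lum: float) -> np.ndarray:
    """LMS absorptions of a scaled-MB point at a given luminance.

    Under the mb_scaled fundamentals L + M = V′, so total L + M absorption is
    luminance / 683; chromaticity then fixes the split linearly.
    """
    rmb, bmb = cs.unscale_mb(p)
    lm_sum = lum / cs.MAX_LUMINOUS_EFFICACY
    return np.array([rmb * lm_sum, (1.0 - rmb) * lm_sum, bmb * lm_sum])


def render_setting(
    h: cs.HueSetting,
    mon: MonitorModel,
    fund: ConeFundamentalSet | None = None,
) -> RGBTriple:
    """Gun drives that reproduce a hue setting's chromaticity and luminance.

    Raises :class:`GamutError` naming the violating gun when the target is
    unreachable.
    """
    fund = fund or task_fundamentals()
    target = _absorption_target(cs.hue_to_scaled_mb(h), h.luminance)
    linear = np.linalg.solve(_gun_matrix(mon.gun_spectra, fund), target)
    names = ("red", "green", "blue")
    for name, v in zip(names, linear):
        if v < -1e-9 or v > 1.0 + 1e-9:
            raise GamutError(f"target requires {name} gun drive {v:.4f} outside [0, 1]")
    linear = np.clip(linear, 0.0, 1.0)
    drives = linear ** (1.0 / mon.gamma)
    return RGBTriple(*map(float, drives))


def monitor_gamut(mon: MonitorModel, filt: FilterModel | None = None) -> np.ndarray:
    """CIE 1931 xy chromaticities of the three gun primaries, shape (3, 2).

    With a filter, the primaries are the filtered gun spectra (the gamut seen
    through the glasses).
    """
    xbar, ybar, zbar = cie1931_cmfs()
    out = []
    for gun in mon.gun_spectra:
        spec = apply_filter(gun, filt) if filt is not None else gun
        X, Y, Z = (
            float(np.sum(spec.resample(xbar.wavelengths).values * c.values))
            for c in (xbar, ybar, zbar)
        )
        total = X + Y + Z
        if total <= 0:
            raise GamutError("gun spectrum has no visible energy")
        out.append((X / total, Y / total))
    return np.asarray(out)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a polygon given as (n, 2) vertices."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Vertex centroid of a polygon."""
    return vertices.mean(axis=0)
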