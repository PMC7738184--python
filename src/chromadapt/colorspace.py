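"""MacLeod-Boynton chromaticity and the scaled isoluminant hue circle.

Cone absorptions (L, M, S) map to MacLeod-Boynton chromaticity

    rmb = L / (L + M)          bmb = S / (L + M)

with the fundamentals of :mod:`chromadapt.fundamentals`, under which CIE
Illuminant C lands at (0.6568, 0.01825).  The task space recentres and
rescales these so that Illuminant C is the origin and one unit approximates
one detection threshold:

    LM = (rmb - 0.6568) * 2168        S = (bmb - 0.01825) * 6210

Stimuli live on a circle of radius 80 threshold units in this plane at a
nominal 51 cd/m²; the response variable is the polar hue angle in degrees
(0° = +LM axis, counterclockwise), with the adjustment task bounded by a
green endpoint at 200° and a red endpoint at 360°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .fundamentals import ConeFundamentalSet, judd_vlambda
from .spectra import Spectrum, common_grid

__all__ = [
    "LMS",
    "MBChromaticity",
    "ScaledMB",
    "HueSetting",
    "WHITE_RMB",
    "WHITE_BMB",
    "LM_SCALE",
    "S_SCALE",
    "HUE_RADIUS",
    "PLANE_LUMINANCE",
    "GREEN_ENDPOINT",
    "RED_ENDPOINT",
    "cone_absorptions",
    "luminance",
    "mb_chromaticity",
    "scale_mb",
    "unscale_mb",
    "hue_to_scaled_mb",
    "scaled_mb_to_hue",
]

WHITE_RMB = 0.6568   #: MacLeod-Boynton rmb of Illuminant C (space origin)
WHITE_BMB = 0.01825  #: MacLeod-Boynton bmb of Illuminant C
LM_SCALE = 2168.0    #: threshold-unit scaling of the red-green axis
S_SCALE = 6210.0     #: threshold-unit scaling of the S axis
HUE_RADIUS = 80.0    #: radius of the task's hue circle, threshold units
PLANE_LUMINANCE = 51.0  #: nominal luminance of the isoluminant plane, cd/m²
GREEN_ENDPOINT = 200.0  #: greenmost reachable hue angle, degrees
RED_ENDPOINT = 360.0    #: redmost reachable hue angle, degrees

MAX_LUMINOUS_EFFICACY = 683.0  # lm/W at the V(lambda) peak


class DegenerateInputError(ValueError):
    """Raised when a chromaticity or angle is undefined for the input."""


class LMS(NamedTuple):
    """Cone absorptions in the linear units of a fundamental set."""

    l: float
    m: float
    s: float


class MBChromaticity(NamedTuple):
    rmb: float
    bmb: float


class ScaledMB(NamedTuple):
    LM: float
    S: float


@dataclass(frozen=True)
class HueSetting:
    """One point on the hue circle.

    Arbitrary angles in [0, 360] are representable (the inverse polar map
    produces them); settings made in the adjustment task itself are confined
    to [200, 360] and can be checked with :meth:`require_task_range`.
    """

    angle: float
    radius: float = HUE_RADIUS
    luminance: float = PLANE_LUMINANCE

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.angle <= 360.0):
            raise ValueError(f"hue angle {self.angle} outside [0, 360]")

    def require_task_range(self) -> "HueSetting":
        if not (GREEN_ENDPOINT <= self.angle <= RED_ENDPOINT):
            raise ValueError(
                f"hue angle {self.angle} outside task range "
                f"[{GREEN_ENDPOINT}, {RED_ENDPOINT}]"
            )
        return self


def cone_absorptions(spec: Spectrum, fund: ConeFundamentalSet) -> LMS:
    """Integrate a radiance spectrum against a fundamental set.

    Rectangle rule at 1 nm on the overlap of the supports; linear in the
    spectrum by construction.
    """
    grid = common_grid(spec, fund.L)
    sv = spec.resample(grid).values
    out = []
    for curve in (fund.L, fund.M, fund.S):
        out.append(float(np.sum(sv * curve.resample(grid).values)))
    return LMS(*out)


def luminance(spec: Spectrum, vlambda: Spectrum | None = None) -> float:
    """Photopic luminance in cd/m², 683 · Σ spec·V′(λ)·Δλ.

    Uses the packaged Judd-modified V(λ) unless another luminosity function
    is supplied.
    """
    if vlambda is None:
        vlambda = judd_vlambda()
    grid = common_grid(spec, vlambda)
    return MAX_LUMINOUS_EFFICACY * float(
        np.sum(spec.resample(grid).values * vlambda.resample(grid).values)
    )


def mb_chromaticity(lms: LMS) -> MBChromaticity:
    """MacLeod-Boynton chromaticity (rmb, bmb) of a cone-absorption triple."""
    denom = lms.l + lms.m
    if denom <= 0:
        raise DegenerateInputError("chromaticity undefined for L + M <= 0")
    return MBChromaticity(lms.l / denom, lms.s / denom)


def scale_mb(c: MBChromaticity) -> ScaledMB:
    """Affine map to the threshold-scaled plane centred on Illuminant C."""
    return ScaledMB((c.rmb - WHITE_RMB) * LM_SCALE, (c.bmb - WHITE_BMB) * S_SCALE)


def unscale_mb(p: ScaledMB) -> MBChromaticity:
    """Exact inverse of :func:`scale_mb`."""
    return MBChromaticity(p.LM / LM_SCALE + WHITE_RMB, p.S / S_SCALE + WHITE_BMB)


def hue_to_scaled_mb(h: HueSetting) -> ScaledMB:
    """Cartesian coordinates of a hue setting on its circle."""
    theta = np.deg2rad(h.angle)
    return ScaledMB(h.radius * float(np.cos(theta)), h.radius * float(np.sin(theta)))


def scaled_mb_to_hue(p: ScaledMB, luminance: float = PLANE_LUMINANCE) -> HueSetting:
    """Polar form of a point in the scaled plane; angle in [0, 360).

    The zero-radius point has no defined angle and raises.
    """
    radius = float(np.hypot(p.LM, p.S))
    if radius == 0.0:
        raise DegenerateInputError("angle undefined at the origin")
    angle = float(np.rad2deg(np.arctan2(p.S, p.LM))) % 360.0
    return HueSetting(angle, radius, luminance)
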