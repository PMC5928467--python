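"""Closed-form leaf area enclosed by a circular gas-exchange gasket.

A cereal leaf narrower than the circular aperture of a clamp-on chamber
(e.g. the 2 cm^2 LI-COR 6400-40 fluorometer head) leaves two empty circle
segments beside its margins.  Treating the margins as parallel chords at
distance ``y = W_L / 2`` from the centre, the enclosed area is

    wA_L = A_G - 2 * (sector(theta) - triangle(y)),

with ``r = sqrt(A_G / pi)``, ``theta = 2 * arccos(y / r)``.  Everything in
this module works in cm / cm^2; angles are radians internally and degrees
in the result record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    InvalidAngleError,
    InvalidAreaError,
    InvalidGasketError,
    InvalidWidthError,
)

logger = logging.getLogger(__name__)

#: Tolerated overshoot of the arccos argument beyond [-1, 1] before it is an error.
_ACOS_SLACK = 1e-9


class AreaMethod(str, Enum):
    """Provenance of an enclosed-area estimate."""

    width_based = "width_based"
    image_based = "image_based"
    oracle = "oracle"


@dataclass(frozen=True)
class GasketSpec:
    """A circular chamber gasket: internal area ``A_G`` and derived radius ``r``."""

    area_AG: float
    radius_r: float = field(init=False)
    shape: str = "circular"

    def __post_init__(self) -> None:
        if not (self.area_AG > 0) or not math.isfinite(self.area_AG):
            raise InvalidGasketError(
                f"gasket area must be a positive finite number of cm^2, got {self.area_AG!r}"
            )
        object.__setattr__(self, "radius_r", radius_from_area(self.area_AG))

    @property
    def diameter(self) -> float:
        """Internal diameter ``2 r`` in cm."""
        return 2.0 * self.radius_r


@dataclass(frozen=True)
class WidthAreaResult:
    """Intermediate and final quantities of the width-based area estimate.

    ``central_angle_theta`` is in degrees; all areas in cm^2.  ``clipped``
    flags the full-coverage case ``W_L >= 2 r`` where the enclosed area is
    the whole gasket.
    """

    width_WL: float
    half_width_y: float
    half_chord_x: float
    central_angle_theta: float
    sector_area: float
    triangle_area: float
    segment_area: float
    enclosed_area_wAL: float
    clipped: bool
    gasket: GasketSpec


@dataclass(frozen=True)
class AreaEstimate:
    """An enclosed-leaf-area value in cm^2 together with how it was obtained."""

    value: float
    method: AreaMethod
    gasket: GasketSpec | None = None


def radius_from_area(area_AG: float) -> float:
    """Internal radius of a circular gasket of area ``A_G``: ``r = sqrt(A_G/pi)``."""
    if not (area_AG > 0) or not math.isfinite(area_AG):
        raise InvalidGasketError(
            f"gasket area must be a positive finite number of cm^2, got {area_AG!r}"
        )
    return math.sqrt(area_AG / math.pi)


#: Built-in gasket presets by catalogue name (6400-40: the circular 2 cm^2
#: leaf chamber fluorometer head).
GASKET_PRESETS: dict[str, GasketSpec] = {
    "6400-40": GasketSpec(area_AG=2.0),
}


def _clamped_acos(argument: float) -> float:
    if argument > 1.0 + _ACOS_SLACK or argument < -1.0 - _ACOS_SLACK:
        raise InvalidWidthError(
            f"arccos argument {argument!r} outside [-1, 1] beyond rounding slack"
        )
    return math.acos(min(1.0, max(-1.0, argument)))


def central_angle(half_width_y: float, radius: float) -> float:
    """Central angle theta (degrees) of the circle sector cut by a chord at
    distance ``y`` from the centre: ``theta = 2 arccos(y/r) * 180/pi``."""
    if radius <= 0:
        raise InvalidGasketError(f"radius must be positive, got {radius!r}")
    if half_width_y < 0:
        raise InvalidWidthError(f"half-width must be non-negative, got {half_width_y!r}")
    if half_width_y > radius * (1.0 + _ACOS_SLACK):
        raise InvalidWidthError(
            f"half-width {half_width_y!r} exceeds gasket radius {radius!r}"
        )
    return math.degrees(2.0 * _clamped_acos(half_width_y / radius))


def sector_area(radius: float, theta_degrees: float) -> float:
    """Circle sector area ``pi r^2 theta / 360`` (theta in degrees)."""
    if radius <= 0:
        raise InvalidGasketError(f"radius must be positive, got {radius!r}")
    if not 0.0 <= theta_degrees <= 360.0:
        raise InvalidAngleError(
            f"central angle must lie in [0, 360] degrees, got {theta_degrees!r}"
        )
    return math.pi * radius * radius * theta_degrees / 360.0


def isosceles_triangle_area(half_width_y: float, radius: float) -> float:
    """Area ``y * sqrt(r^2 - y^2)`` of the isosceles triangle between the two
    radii and the chord at distance ``y`` from the centre."""
    if radius <= 0:
        raise InvalidGasketError(f"radius must be positive, got {radius!r}")
    if half_width_y < 0 or half_width_y > radius * (1.0 + _ACOS_SLACK):
        raise InvalidWidthError(
            f"half-width must lie in [0, r={radius!r}], got {half_width_y!r}"
        )
    under = max(0.0, radius * radius - half_width_y * half_width_y)
    return half_width_y * math.sqrt(under)


def segment_area(half_width_y: float, radius: float) -> float:
    """Circle segment area beyond a chord at distance ``y``: sector minus triangle."""
    theta = central_angle(half_width_y, radius)
    area = sector_area(radius, theta) - isosceles_triangle_area(half_width_y, radius)
    return max(0.0, area)


def width_area_closed_form(width_WL: float, area_AG: float) -> float:
    """Single-expression enclosed area in terms of ``W_L`` and ``A_G`` only.

    Algebraically identical to the stepwise sector/triangle/segment route;
    kept separate so the two can be cross-checked.  Not clipped: valid for
    ``0 <= W_L <= 2 sqrt(A_G/pi)``.
    """
    r = radius_from_area(area_AG)
    arg = width_WL / (2.0 * r)
    return (
        area_AG
        - 2.0 * area_AG * _clamped_acos(arg) / math.pi
        + width_WL * math.sqrt(max(0.0, area_AG / math.pi - width_WL * width_WL / 4.0))
    )


def width_based_area(width_WL: float, gasket: GasketSpec) -> WidthAreaResult:
    """Enclosed leaf area from a single mid-chord leaf width.

    Assumes the leaf midrib passes through the gasket centre with margins
    parallel to it; the two empty circle segments beside the margins are
    subtracted from the gasket area.  Widths at or above the internal
    diameter mean full coverage: the gasket area is returned with
    ``clipped=True`` (and a log warning), since that is the case the
    instrument already assumes.
    """
    if width_WL < 0 or not math.isfinite(width_WL):
        raise InvalidWidthError(f"leaf width must be a non-negative number of cm, got {width_WL!r}")
    r = gasket.radius_r
    if width_WL >= 2.0 * r:
        if width_WL > 2.0 * r:
            logger.warning(
                "leaf width %.4f cm >= gasket internal diameter %.4f cm; "
                "full coverage assumed (enclosed area = gasket area)",
                width_WL,
                2.0 * r,
            )
        return WidthAreaResult(
            width_WL=width_WL,
            half_width_y=min(width_WL / 2.0, r),
            half_chord_x=0.0,
            central_angle_theta=0.0,
            sector_area=0.0,
            triangle_area=0.0,
            segment_area=0.0,
            enclosed_area_wAL=gasket.area_AG,
            clipped=True,
            gasket=gasket,
        )
    y = width_WL / 2.0
    x = math.sqrt(max(0.0, r * r - y * y))
    theta = central_angle(y, r)
    sector = sector_area(r, theta)
    triangle = isosceles_triangle_area(y, r)
    segment = max(0.0, sector - triangle)
    enclosed = gasket.area_AG - 2.0 * segment
    enclosed = min(max(enclosed, 0.0), gasket.area_AG)
    return WidthAreaResult(
        width_WL=width_WL,
        half_width_y=y,
        half_chord_x=x,
        central_angle_theta=theta,
        sector_area=sector,
        triangle_area=triangle,
        segment_area=segment,
        enclosed_area_wAL=enclosed,
        clipped=False,
        gasket=gasket,
    )


def uncorrected_error_percent(measured_area_AL: float, gasket: GasketSpec) -> float:
    """Percent error in any per-area rate if the instrument's assumed area
    (the gasket area) is used instead of the true enclosed area ``A_L``:
    ``100 (A_G / A_L - 1)``."""
    if not (measured_area_AL > 0) or not math.isfinite(measured_area_AL):
        raise InvalidAreaError(
            f"measured leaf area must be positive, got {measured_area_AL!r}"
        )
    return 100.0 * (gasket.area_AG / measured_area_AL - 1.0)
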