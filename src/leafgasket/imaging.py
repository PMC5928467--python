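"""Image-based enclosed leaf area (iA_L).

Automates the manual tracing workflow for photographs of a leaf laid under
a printed, to-scale impression of the chamber gasket on white paper:

1. calibrate the pixel scale from a printed 1 cm bar,
2. locate the gasket-impression circle (Hough vote over ink pixels,
   algebraic circle refit, inner-edge aperture radius),
3. segment leaf pixels inside the aperture (Otsu on the in-circle
   histogram, rim-ink exclusion, morphological cleanup, largest component),
4. convert the pixel count to cm^2.

Printed ink (bar, impression ring) is assumed near-black while leaf tissue
is a mid tone; segmentation only requires the leaf to be darker than the
white ground.  A pixel belongs to the aperture disc if its centre lies
inside the circle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing as _closing, disk
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import (
    AmbiguousContrastError,
    CircleNotFoundError,
    InvalidGasketError,
    ScaleNotFoundError,
)
from .geometry import AreaEstimate, AreaMethod, GasketSpec
from .synthetic import MIN_PX_PER_CM

#: Grey level below which a pixel is treated as printed ink (0..255 scale).
INK_THRESHOLD = 64.0

#: Minimum bounding-box aspect ratio for a component to qualify as the bar.
BAR_MIN_ASPECT = 5.0

#: Minimum normalized Hough accumulator vote to accept a circle: at least
#: half the candidate perimeter must be supported by ink (a straight bar can
#: muster ~0.3 via tangent circles; a printed ring scores near 1).
CIRCLE_MIN_VOTE = 0.5

#: Width (px) of the rim band where near-black pixels are treated as the
#: printed impression rather than leaf.
RIM_BAND_PX = 2.0

_LUMINANCE = np.array([0.2126, 0.7152, 0.0722])


class EmptyLeafWarning(UserWarning):
    """Raised (as a warning) when essentially no leaf is found in the aperture."""


class LowResolutionWarning(UserWarning):
    """Image resolution below the supported minimum of 50 px/cm."""


@dataclass(frozen=True)
class LeafImageScene:
    """A calibrated raster with the gasket circle located in pixel space."""

    pixels: np.ndarray  # 2-D float grayscale, 0..255, origin top-left
    px_per_cm: float
    gasket_circle: tuple[float, float, float]  # (center_row, center_col, radius_px)
    provenance: str = "detected"  # or "user_supplied"
    gasket: GasketSpec | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("scene pixels must be a 2-D grayscale raster")
        if not self.px_per_cm > 0:
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm!r}")
        cr, cc, radius = self.gasket_circle
        h, w = self.pixels.shape
        if radius <= 0 or cr - radius < -0.5 or cc - radius < -0.5 or \
                cr + radius > h - 0.5 or cc + radius > w - 0.5:
            raise ValueError(
                f"gasket circle {self.gasket_circle} does not lie inside the "
                f"{h}x{w} image"
            )
        if self.px_per_cm < MIN_PX_PER_CM:
            warnings.warn(
                f"resolution {self.px_per_cm:.1f} px/cm is below the supported "
                f"minimum of {MIN_PX_PER_CM} px/cm; areas may be unreliable",
                LowResolutionWarning,
                stacklevel=2,
            )
        if self.gasket is not None:
            implied = math.pi * (radius / self.px_per_cm) ** 2
            if abs(implied - self.gasket.area_AG) > 0.02 * self.gasket.area_AG:
                raise InvalidGasketError(
                    f"detected circle implies an aperture of {implied:.4f} cm^2, "
                    f"more than 2% away from the declared gasket area "
                    f"{self.gasket.area_AG:.4f} cm^2"
                )

    @property
    def aperture_area_cm2(self) -> float:
        return math.pi * (self.gasket_circle[2] / self.px_per_cm) ** 2


@dataclass(frozen=True)
class LeafMask:
    """Binary leaf mask inside the aperture disc."""

    mask: np.ndarray  # bool, same shape as the scene
    pixel_count: int
    area_cm2: float


@dataclass(frozen=True)
class ImagingResult:
    """Area estimate plus the audit trail (scene geometry and mask)."""

    estimate: AreaEstimate
    scene: LeafImageScene
    mask: LeafMask


def load_image(source, channel: str = "luminance") -> np.ndarray:
    """Read PNG/TIFF/JPEG (or accept an array) as float grayscale 0..255.

    RGB inputs collapse to Rec.709 luminance by default; ``channel='green'``
    uses the green plane alone, often the highest-contrast choice for leaves.
    """
    if isinstance(source, (str, Path)):
        with Image.open(source) as im:
            arr = np.asarray(im)
    else:
        arr = np.asarray(source)
    arr = arr.astype(float)
    if arr.ndim == 3:
        if channel == "green":
            arr = arr[..., 1]
        else:
            arr = arr[..., :3] @ _LUMINANCE
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    if arr.max() <= 1.0:  # normalized floats
        arr = arr * 255.0
    return arr


def calibrate_scale(
    image: np.ndarray,
    bar_length_cm: float = 1.0,
    bar_roi: tuple[int, int, int, int] | None = None,
) -> float:
    """Pixel scale from the printed bar: px_per_cm = bar extent / length.

    The bar is found as the largest near-black connected component whose
    bounding box has aspect ratio >= 5; its extent is the long box side.
    ``bar_roi`` = (row0, row1, col0, col1) restricts the search.
    """
    if bar_length_cm <= 0:
        raise ValueError(f"bar length must be positive, got {bar_length_cm!r}")
    region = image
    if bar_roi is not None:
        r0, r1, c0, c1 = bar_roi
        region = image[r0:r1, c0:c1]
    ink = region < INK_THRESHOLD
    best = None
    for props in regionprops(label(ink)):
        r0, c0, r1, c1 = props.bbox
        long_side, short_side = max(r1 - r0, c1 - c0), min(r1 - r0, c1 - c0)
        if short_side == 0 or long_side / short_side < BAR_MIN_ASPECT:
            continue
        if best is None or props.area > best[0]:
            best = (props.area, long_side)
    if best is None:
        raise ScaleNotFoundError(
            "no scale bar found (no near-black component with aspect ratio >= 5); "
            "pass the pixel scale explicitly"
        )
    return best[1] / bar_length_cm


def _kasa_circle_fit(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit; returns (center_row, center_col, radius)."""
    a = np.column_stack([2.0 * rows, 2.0 * cols, np.ones_like(rows)])
    b = rows**2 + cols**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cr, cc, c = sol
    return float(cr), float(cc), float(math.sqrt(max(0.0, c + cr * cr + cc * cc)))


def locate_gasket_circle(
    image: np.ndarray,
    expected_radius_px: float | None = None,
) -> tuple[float, float, float]:
    """Find the gasket-impression circle; returns (center_row, center_col,
    aperture_radius_px).

    Ink pixels vote in a circular Hough accumulator (radius search +-15%
    around ``expected_radius_px`` when given, else a coarse-then-fine
    sweep).  The winning circle's centre is refined by an algebraic fit to
    the ink pixels near the ring, and the aperture radius is taken at the
    ring's inner edge (2nd percentile of radial ink distances), since the
    printed outline marks the aperture from outside.
    """
    ink = image < INK_THRESHOLD
    if not ink.any():
        raise CircleNotFoundError(
            "no ink pixels in the image; pass the circle explicitly"
        )
    h, w = image.shape
    r_cap = int(min(h, w) / 2)
    if expected_radius_px is not None:
        lo = max(5, int(0.85 * expected_radius_px))
        hi = min(r_cap, int(math.ceil(1.15 * expected_radius_px)))
        radii = np.arange(lo, max(hi, lo + 1) + 1, 2)
    else:
        radii = np.arange(max(10, int(0.05 * min(h, w))), max(r_cap, 12), 2)

    def _peak(rads_grid):
        accum = hough_circle(ink, rads_grid)
        votes, ccs, crs, rads = hough_circle_peaks(accum, rads_grid, total_num_peaks=1)
        if len(votes) == 0:
            raise CircleNotFoundError("empty Hough accumulator")
        return float(votes[0]), float(crs[0]), float(ccs[0]), float(rads[0])

    _, _, _, r_coarse = _peak(radii)
    # fine pass at 1 px steps around the coarse winner; a 2 px printed ring
    # can fall between coarser radius samples
    vote, cr0, cc0, r0 = _peak(np.arange(max(5, int(r_coarse) - 3), int(r_coarse) + 4))
    if vote < CIRCLE_MIN_VOTE:
        raise CircleNotFoundError(
            "no circular outline found (peak Hough vote below threshold); "
            "pass the circle explicitly"
        )

    rows, cols = np.nonzero(ink)
    dist = np.hypot(rows - cr0, cols - cc0)
    near = np.abs(dist - r0) <= 4.0
    if near.sum() < 16:
        raise CircleNotFoundError("too few ink pixels near the candidate ring")
    cr, cc, _ = _kasa_circle_fit(rows[near].astype(float), cols[near].astype(float))
    refined = np.hypot(rows[near] - cr, cols[near] - cc)
    aperture_radius = float(np.percentile(refined, 2.0))
    return cr, cc, aperture_radius


def segment_leaf(scene: LeafImageScene) -> LeafMask:
    """Segment leaf pixels inside the aperture.

    Otsu's threshold is computed on pixels strictly inside the circle
    (excluding a 2 px rim band so the printed outline cannot bias the
    histogram); darker-than-threshold pixels are kept, near-black rim
    pixels (printed ink) are dropped, then morphological closing and
    largest-connected-component selection clean the mask.

    When the in-circle histogram is effectively unimodal (Otsu class means
    closer than 15% of the dynamic range) the aperture is classified
    wholesale against the white ground outside the circle: full leaf
    coverage or an empty aperture.
    """
    pix = scene.pixels
    cr, cc, r_ap = scene.gasket_circle
    rows = np.arange(pix.shape[0])[:, None]
    cols = np.arange(pix.shape[1])[None, :]
    dist = np.hypot(rows - cr, cols - cc)
    disc = dist < r_ap
    interior = dist < r_ap - RIM_BAND_PX
    px_per_cm = scene.px_per_cm

    def _finish(mask: np.ndarray) -> LeafMask:
        count = int(mask.sum())
        return LeafMask(mask=mask, pixel_count=count, area_cm2=count / px_per_cm**2)

    inside = pix[interior]
    thr = float(threshold_otsu(inside))
    # place the cut midway between the class means (fixpoint); Otsu's binned
    # threshold can fall inside a histogram spike on strongly quantized input
    for _ in range(64):
        lo, hi = inside[inside < thr], inside[inside >= thr]
        if lo.size == 0 or hi.size == 0:
            break
        new_thr = 0.5 * (float(lo.mean()) + float(hi.mean()))
        if abs(new_thr - thr) < 0.5:
            thr = new_thr
            break
        thr = new_thr
    below, above = inside[inside < thr], inside[inside >= thr]
    bimodal = below.size and above.size and \
        (above.mean() - below.mean()) >= 0.15 * 255.0
    if not bimodal:
        outside = pix[dist > r_ap + RIM_BAND_PX + 1]
        white_ref = float(np.percentile(outside, 75)) if outside.size else 255.0
        if float(np.median(inside)) < 0.7 * white_ref:
            return _finish(disc)  # uniform dark: full coverage
        warnings.warn(
            "no leaf found inside the gasket aperture", EmptyLeafWarning, stacklevel=2
        )
        return _finish(np.zeros_like(disc))

    fg = (pix < thr) & disc
    rim_ink = (pix < INK_THRESHOLD) & (dist >= r_ap - RIM_BAND_PX)
    fg &= ~rim_ink
    frac = fg.sum() / max(disc.sum(), 1)
    if frac < 0.005:
        warnings.warn(
            "foreground below 0.5% of the aperture; treating as empty",
            EmptyLeafWarning,
            stacklevel=2,
        )
        return _finish(np.zeros_like(disc))
    if frac > 0.995:
        raise AmbiguousContrastError(
            "segmentation foreground fills >99.5% of the aperture despite a "
            "bimodal histogram; leaf/background contrast is ambiguous"
        )
    fg = _closing(fg, disk(2)) & disc
    lab = label(fg)
    if lab.max() > 0:
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        fg = lab == largest
    return _finish(fg)


def image_based_area(
    source,
    gasket: GasketSpec | None = None,
    px_per_cm: float | None = None,
    circle: tuple[float, float, float] | None = None,
    bar_length_cm: float = 1.0,
    bar_roi: tuple[int, int, int, int] | None = None,
    channel: str = "luminance",
) -> ImagingResult:
    """Full pipeline: scale calibration, circle location, segmentation, iA_L.

    ``px_per_cm`` and ``circle`` override the respective detection stages
    (every detection failure is recoverable by passing them explicitly).
    """
    image = load_image(source, channel=channel)
    if px_per_cm is None:
        px_per_cm = calibrate_scale(image, bar_length_cm=bar_length_cm, bar_roi=bar_roi)
    if circle is None:
        expected = gasket.radius_r * px_per_cm if gasket is not None else None
        circle = locate_gasket_circle(image, expected_radius_px=expected)
        provenance = "detected"
    else:
        provenance = "user_supplied"
    scene = LeafImageScene(
        pixels=image,
        px_per_cm=px_per_cm,
        gasket_circle=tuple(float(v) for v in circle),
        provenance=provenance,
        gasket=gasket,
    )
    mask = segment_leaf(scene)
    estimate = AreaEstimate(
        value=mask.area_cm2, method=AreaMethod.image_based, gasket=gasket
    )
    return ImagingResult(estimate=estimate, scene=scene, mask=mask)


def save_mask(mask: LeafMask, path) -> None:
    """Write the leaf mask as an 8-bit PNG (255 = leaf)."""
    Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)
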