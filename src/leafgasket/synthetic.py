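"""Synthetic cereal leaves, rendered gasket scenes and instrument logs.

Everything downstream (geometry, imaging, log correction, agreement
statistics) is validated against this module: it provides a parametric
blade width profile, a numerically integrated enclosed-area oracle that is
independent of the closed-form geometry, a rendered image of the leaf under
a printed gasket impression with a 1 cm scale bar, and internally
consistent tab-delimited gas-exchange logs.

Rendering conventions (deliberate, and relied on by the imaging module's
defaults): printed ink -- the scale bar and the impression ring -- is
near-black; leaf tissue is mid-grey on a white ground, with the midrib a
little darker than the lamina.  The impression ring is drawn as a 2 px
annulus immediately *outside* the aperture, the way a printed outline marks
a boundary from without.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .errors import LayoutError, ParameterError
from .geometry import GasketSpec

# Grey levels (0..255) used by the renderer.
INK_LEVEL = 0
LAMINA_LEVEL = 107
BACKGROUND_LEVEL = 255
MIDRIB_DARKENING = 0.10  # midrib rendered 10% darker than the lamina

#: Minimum raster resolution accepted by the renderer and imaging pipeline.
MIN_PX_PER_CM = 50

FAMILIES = ("constant", "linear", "lanceolate")

#: Blade archetypes (base width cm, taper rate, blade length cm, family).
#: Widths follow the familiar ordering maize > barley > hard wheat > soft
#: wheat; the numbers are synthetic presets, not calibrated species data.
ARCHETYPES: dict[str, dict] = {
    "maize-like": dict(family="lanceolate", base_width_cm=1.4, taper_rate=0.5, length_cm=40.0),
    "barley-like": dict(family="lanceolate", base_width_cm=0.7, taper_rate=0.6, length_cm=25.0),
    "hard-wheat-like": dict(family="linear", base_width_cm=0.5, taper_rate=0.4, length_cm=20.0),
    "soft-wheat-like": dict(family="linear", base_width_cm=0.4, taper_rate=0.4, length_cm=18.0),
}


@dataclass(frozen=True)
class SyntheticLeaf:
    """Parametric blade: width ``W(s)`` (cm) versus arc position ``s`` (cm)
    from the blade base, symmetric about the midrib.

    Families: ``constant`` (parallel margins), ``linear`` (straight,
    converging margins -- a long trapezoid) and ``lanceolate`` (quadratic
    taper, curved margins).
    """

    family: str
    base_width_cm: float
    taper_rate: float
    length_cm: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown leaf family {self.family!r}; choose from {FAMILIES}")
        if not 0.0 < self.base_width_cm <= 2.0:
            raise ParameterError(
                f"base width must lie in (0, 2] cm, got {self.base_width_cm!r}"
            )
        if self.taper_rate < 0:
            raise ParameterError(f"taper rate must be >= 0, got {self.taper_rate!r}")
        if self.length_cm <= 0:
            raise ParameterError(f"blade length must be positive, got {self.length_cm!r}")

    def width(self, s) -> np.ndarray:
        """Blade width (cm) at arc position(s) ``s``; zero outside [0, L]."""
        s = np.asarray(s, dtype=float)
        t = s / self.length_cm
        if self.family == "constant":
            w = np.full_like(t, self.base_width_cm)
        elif self.family == "linear":
            w = self.base_width_cm * (1.0 - self.taper_rate * t)
        else:  # lanceolate: quadratic margin curvature
            w = self.base_width_cm * (1.0 - self.taper_rate * t * t)
        w = np.where((t < 0) | (t > 1), 0.0, w)
        return np.maximum(w, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Numerical-oracle truth for one leaf/gasket placement."""

    true_enclosed_area: float  # cm^2
    mid_chord_width: float  # cm, what a caliper at the gasket centre reads


def generate_leaf(
    family: str,
    base_width_cm: float,
    taper_rate: float = 0.0,
    length_cm: float = 20.0,
    seed: int = 0,
) -> SyntheticLeaf:
    """Construct a leaf; deterministic for a fixed parameter set and seed."""
    return SyntheticLeaf(
        family=family,
        base_width_cm=base_width_cm,
        taper_rate=taper_rate,
        length_cm=length_cm,
        seed=seed,
    )


def sample_archetype(name: str, rng: np.random.Generator) -> SyntheticLeaf:
    """Draw one leaf from a named archetype with mild biological jitter
    (+-8% base width, +-20% taper)."""
    if name not in ARCHETYPES:
        raise ParameterError(f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}")
    base = ARCHETYPES[name]
    width = base["base_width_cm"] * float(rng.uniform(0.92, 1.08))
    taper = base["taper_rate"] * float(rng.uniform(0.8, 1.2))
    return SyntheticLeaf(
        family=base["family"],
        base_width_cm=min(width, 2.0),
        taper_rate=taper,
        length_cm=base["length_cm"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def true_enclosed_area(
    leaf: SyntheticLeaf,
    gasket: GasketSpec,
    center_position_s: float,
    panels: int = 20_000,
) -> GroundTruth:
    """Enclosed leaf area by direct 1-D quadrature -- the oracle.

    The leaf runs along the chord through the gasket centre at arc position
    ``s0 = center_position_s``; at offset ``u`` from the centre the covered
    chord height is ``min(W(s0+u), 2 sqrt(r^2-u^2))``.  Composite-Simpson
    integration over ``u in [-r, r]``; a half-resolution pass bounds the
    quadrature error (Richardson check, <= 1e-5 cm^2).
    """
    r = gasket.radius_r

    def integrand(n: int) -> float:
        u = np.linspace(-r, r, 2 * n + 1)
        chord = 2.0 * np.sqrt(np.maximum(0.0, r * r - u * u))
        covered = np.minimum(leaf.width(center_position_s + u), chord)
        h = (2.0 * r) / (2 * n)
        weights = np.ones_like(u)
        weights[1:-1:2] = 4.0
        weights[2:-1:2] = 2.0
        return float(h / 3.0 * np.sum(weights * covered))

    fine = integrand(panels)
    coarse = integrand(panels // 2)
    if abs(fine - coarse) > 1e-5:
        # one refinement; the integrand kinks where leaf meets rim
        fine = integrand(4 * panels)
    area = min(max(fine, 0.0), gasket.area_AG)
    width_mid = float(leaf.width(center_position_s))
    return GroundTruth(true_enclosed_area=area, mid_chord_width=width_mid)


@dataclass(frozen=True)
class RenderedScene:
    """A rendered raster plus everything the renderer knows to be true."""

    image: np.ndarray  # uint8, grayscale
    truth: GroundTruth
    px_per_cm: float
    circle: tuple[int, int, float]  # (center_row, center_col, aperture_radius_px)
    bar_bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    gasket: GasketSpec


def render_scene(
    leaf: SyntheticLeaf | None,
    gasket: GasketSpec,
    px_per_cm: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    center_position_s: float | None = None,
    midrib: bool = True,
) -> RenderedScene:
    """Render the leaf under a printed gasket impression with a 1 cm bar.

    White ground; mid-grey leaf strip crossing the frame horizontally with
    anti-aliased margins; near-black 2 px impression annulus just outside
    the aperture; near-black 1 cm scale bar below the circle.  ``noise_sd``
    is additive Gaussian noise as a fraction of the 0..255 dynamic range;
    the render is deterministic per seed.  ``leaf=None`` renders an empty
    aperture (no leaf at all).
    """
    if px_per_cm < MIN_PX_PER_CM:
        raise ParameterError(
            f"px_per_cm={px_per_cm!r} below the supported minimum of {MIN_PX_PER_CM}"
        )
    if center_position_s is None:
        center_position_s = leaf.length_cm / 2.0 if leaf is not None else 0.0
    r_px = gasket.radius_r * px_per_cm
    margin = int(round(0.35 * px_per_cm))
    bar_len = int(round(px_per_cm))  # exactly 1 cm of pixels
    bar_thick = max(4, int(round(0.04 * px_per_cm)))
    bar_gap = int(round(0.25 * px_per_cm))

    cr = margin + int(math.ceil(r_px)) + 2
    cc_min_for_bar = bar_len + 2 * margin
    width_px = max(2 * (margin + int(math.ceil(r_px)) + 2), cc_min_for_bar) + 2 * margin
    cc = width_px // 2
    height_px = cr + int(math.ceil(r_px)) + 2 + bar_gap + bar_thick + margin

    img = np.full((height_px, width_px), float(BACKGROUND_LEVEL))

    # leaf strip with anti-aliased margins (coverage-shaded edge pixels)
    cols = np.arange(width_px)
    if leaf is not None:
        s = center_position_s + (cols - cc) / px_per_cm
        half_w_px = leaf.width(s) * px_per_cm / 2.0
    else:
        half_w_px = np.zeros(width_px)
    rows = np.arange(height_px, dtype=float)[:, None]
    dr = np.abs(rows - cr)
    coverage = np.clip(half_w_px[None, :] - dr + 0.5, 0.0, 1.0)
    coverage[:, half_w_px <= 0.0] = 0.0  # no blade at this column
    img = np.minimum(img, BACKGROUND_LEVEL - coverage * (BACKGROUND_LEVEL - LAMINA_LEVEL))
    if midrib and leaf is not None:
        mid_half = 0.08 * half_w_px
        midrib_cov = np.clip(mid_half[None, :] - dr + 0.5, 0.0, 1.0)
        midrib_cov[:, half_w_px <= 0.0] = 0.0
        midrib_level = LAMINA_LEVEL * (1.0 - MIDRIB_DARKENING)
        img = np.minimum(
            img, BACKGROUND_LEVEL - midrib_cov * (BACKGROUND_LEVEL - midrib_level)
        )

    # impression ring: ink on the 2 px annulus immediately outside the aperture
    rr = np.arange(height_px)[:, None]
    ccs = np.arange(width_px)[None, :]
    dist = np.hypot(rr - cr, ccs - cc)
    ring = (dist >= r_px) & (dist < r_px + 2.0)
    img[ring] = INK_LEVEL

    # scale bar, centred below the circle
    bar_r0 = cr + int(math.ceil(r_px)) + 2 + bar_gap
    bar_r1 = bar_r0 + bar_thick
    bar_c0 = cc - bar_len // 2
    bar_c1 = bar_c0 + bar_len
    if bar_r1 + 1 >= height_px or bar_c0 < 0 or bar_c1 > width_px:
        raise LayoutError("scale bar does not fit the rendered frame")
    leaf_rows_max = cr + int(math.ceil(half_w_px.max())) + 1
    if bar_r0 <= leaf_rows_max or bar_r0 <= cr + r_px + 2:
        raise LayoutError("scale bar overlaps the leaf strip or the impression ring")
    img[bar_r0:bar_r1, bar_c0:bar_c1] = INK_LEVEL

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd * 255.0, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if leaf is not None:
        truth = true_enclosed_area(leaf, gasket, center_position_s)
    else:
        truth = GroundTruth(true_enclosed_area=0.0, mid_chord_width=0.0)
    return RenderedScene(
        image=image,
        truth=truth,
        px_per_cm=px_per_cm,
        circle=(cr, cc, r_px),
        bar_bbox=(bar_r0, bar_r1, bar_c0, bar_c1),
        gasket=gasket,
    )


# ---------------------------------------------------------------------------
# instrument logs

LOG_COLUMNS = ["Obs", "HHMMSS", "Area", "Photo", "Cond", "Trmmol", "Ci", "PhiPS2", "Label"]

# plausible steady-state ranges for a cereal leaf at moderate light
_RANGES = {
    "Photo": (2.0, 25.0),  # umol CO2 m-2 s-1
    "Cond": (0.05, 0.5),  # mol H2O m-2 s-1
    "Trmmol": (0.5, 8.0),  # mmol H2O m-2 s-1
    "Ci": (200.0, 350.0),  # umol mol-1
    "PhiPS2": (0.4, 0.8),
}


@dataclass(frozen=True)
class LogBundle:
    """A synthetic instrument log and its per-row area annotation sidecar."""

    log_text: str
    annotation_text: str | None


def generate_log(
    n_rows: int,
    gasket: GasketSpec,
    seed: int = 0,
    al_values=None,
    label_prefix: str = "leaf",
) -> LogBundle:
    """Tab-delimited gas-exchange log with banner lines before the header.

    Per-area rates are drawn uniformly from plausible steady-state ranges;
    the instrument's ``Area`` column is the gasket area (its default
    assumption).  ``al_values``, when given, must have one true enclosed
    area per row and is emitted as a ``label,AL_cm2`` annotation file.
    Byte-identical output for a fixed seed.
    """
    if n_rows < 1:
        raise ParameterError(f"n_rows must be >= 1, got {n_rows!r}")
    if al_values is not None and len(al_values) != n_rows:
        raise ParameterError(
            f"al_values has {len(al_values)} entries for {n_rows} log rows"
        )
    rng = np.random.default_rng(seed)
    lines = [
        '"Synthetic gas exchange log"',
        f'"Const: gasket area = {gasket.area_AG:g} cm2"',
        "\t".join(LOG_COLUMNS),
    ]
    for i in range(n_rows):
        vals = {k: rng.uniform(lo, hi) for k, (lo, hi) in _RANGES.items()}
        t = 8 * 3600 + 90 * i
        row = [
            str(i + 1),
            f"{t // 3600:02d}:{t % 3600 // 60:02d}:{t % 60:02d}",
            f"{gasket.area_AG:.2f}",
            f"{vals['Photo']:.4f}",
            f"{vals['Cond']:.5f}",
            f"{vals['Trmmol']:.4f}",
            f"{vals['Ci']:.2f}",
            f"{vals['PhiPS2']:.4f}",
            f"{label_prefix}{i + 1:03d}",
        ]
        lines.append("\t".join(row))
    log_text = "\n".join(lines) + "\n"

    annotation_text = None
    if al_values is not None:
        ann = ["label,AL_cm2"]
        ann += [
            f"{label_prefix}{i + 1:03d},{float(a):.6f}" for i, a in enumerate(al_values)
        ]
        annotation_text = "\n".join(ann) + "\n"
    return LogBundle(log_text=log_text, annotation_text=annotation_text)
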