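# Methods

## The problem

Clamp-on gas exchange chambers report per-area rates using the internal
gasket aperture area A_G as the leaf area, valid only when the leaf covers
the aperture completely.  For a leaf of true enclosed area A_L < A_G, each
reported per-area rate is too small by the factor A_L/A_G; equivalently,
neglecting the correction inflates nothing and deflates everything by
100·(A_G/A_L − 1) percent once the rates are referred to the true area.
The package provides two estimators of A_L for circular gaskets, the
correction itself, and the statistics used to compare the estimators.

## Width-based geometry

Assumptions: the leaf midrib passes through the gasket centre ("centred"
placement), and the two margins are straight lines parallel to the midrib
at distance y = W_L/2.  Then the uncovered region consists of two
congruent circle segments.  With r = √(A_G/π) and the central angle
θ = 2·arccos(y/r):

- sector area = πr²·θ°/360°
- isosceles triangle area = y·√(r²−y²)
- segment area = sector − triangle
- enclosed area wA_L = A_G − 2·segment

`width_based_area` builds the result stepwise (each intermediate is
reported for audit); `width_area_closed_form` is the equivalent one-line
expression in W_L and A_G only, kept separate so the two routes can be
cross-checked (they agree to 1e−10 cm² in tests).  Angles are radians
internally; the result record carries θ in degrees.

Why the parallel-margin assumption is mild: over the chord of length 2x
that the blade crosses, a tapering blade is a trapezoid whose area depends
only on its median width and height — and W_L measured at the gasket
centre *is* that median.  The residual error comes only from margin
curvature across the chord, second-order for realistic cereal taper.  The
synthetic suite quantifies it: for the four blade archetypes the formula
tracks the quadrature oracle within 5%, and typically within a fraction of
a percent.

Degenerate inputs: W_L ≥ 2r is full coverage; the function returns A_G
with `clipped=True` and logs a warning rather than erroring, since that is
the case the instrument already assumes.  The arccos argument is clamped
to [−1, 1] only within 1e−9 slack; anything further out is an error, so
unit mistakes (mm passed as cm) cannot be silently absorbed.  Units are
cm/cm² throughout the library; the CLI's `--units mm` converts on input.
Off-centre placement is not modelled (known limitation; the imaging route
has no such assumption).

## Image-based pipeline

The pipeline automates the manual procedure of tracing the leaf inside a
printed gasket impression and reads out iA_L in cm²:

1. **Scale.**  The printed 1 cm bar is found as the largest near-black
   connected component with bounding-box aspect ratio ≥ 5; its long-side
   extent divided by the bar length gives px_per_cm.  The near-black
   criterion (grey < 64/255) deliberately keys on *ink*: leaf tissue is a
   mid tone, so a leaf strip crossing the frame can never be mistaken for
   the bar.
2. **Circle.**  Ink pixels vote in a circular Hough accumulator (radius
   sweep ±15% around the expected radius when a gasket is declared, else
   coarse-then-fine).  A candidate is accepted only if at least half its
   perimeter is supported by ink — a straight bar musters at most ~0.3 via
   tangent circles, a printed ring scores near 1.  The centre is then
   refined by an algebraic (Kasa) circle fit to the ring ink, and the
   aperture radius is taken at the ring's inner edge (2nd percentile of
   radial ink distances), because a printed outline marks the aperture
   from outside.  This keeps the full-coverage case accurate without
   sacrificing a rim-erosion band of area.
3. **Segmentation.**  Otsu's threshold is computed on pixels strictly
   inside the circle (a 2 px rim band excluded so the outline cannot bias
   the histogram), and the cut is then moved to the midpoint between the
   two class means (fixpoint iteration): Otsu's binned threshold can land
   inside a histogram spike on strongly quantized images, and the
   class-mean fixpoint is insensitive to that.  Darker-than-threshold
   pixels inside the disc are kept; near-black pixels in the rim band are
   removed as printed ink; morphological closing (disc, radius 2 px) and
   largest-connected-component selection finish the mask.  A pixel belongs
   to the aperture if its centre lies inside the circle; area =
   count / px_per_cm².
4. **Uniform apertures.**  When the in-circle histogram is effectively
   unimodal (class means closer than 15% of the dynamic range) a threshold
   is meaningless; the aperture is classified wholesale against the white
   ground outside the circle (median inside < 0.7 × outside reference ⇒
   full coverage; otherwise empty, with a warning).  Without this guard
   the two limiting cases — leaf covering everything, no leaf at all —
   would be decided by thresholding noise.

Failure modes are explicit and recoverable: scale-not-found, circle-not-
found and ambiguous-contrast errors all carry instructions, and
`image_based_area` accepts `px_per_cm` and `circle` overrides.  RGB input
collapses to Rec.709 luminance by default (`channel="green"` available).
Minimum supported resolution is 50 px/cm (warning below).  No perspective
correction is attempted: the leaf is assumed flat under the impression.

**Accuracy floor.**  The mask is binary, so each margin is localized to
one pixel row per column; the relative quantization error of the area is
bounded by roughly 1/(W_L·px_per_cm) — at the default 150 px/cm, under 1%
for blades wider than ~0.7 cm and ~2% at 0.4 cm.  Sensor noise dithers
the anti-aliased margins and in practice *reduces* the systematic part of
this error.  Higher resolution tightens the bound linearly.

## Correction of instrument logs

The correction is pure area rescaling: every per-area rate (P_N, g_s, E)
is multiplied by S/A_L, where S is the area the instrument divided by
(its gasket default).  This is exactly the identity that makes molar flux
(rate × area) invariant, and it is how corrected g_s is obtained here; no
re-derivation of conductance from raw H₂O differentials with
boundary-layer re-estimation is attempted (documented limitation for
users needing a full recomputation chain).  iWUE = P_N/g_s is invariant
because numerator and denominator scale identically.  C_i is passed
through unchanged with a `ci_uncorrected` flag — its computation mixes
fluxes whose area terms cancel only approximately, and pass-through is
the conservative choice.  Φ_PSII is a fluorescence ratio, independent of
the area assumption, and is carried unchanged.  A_L > S is refused: a
leaf cannot exceed the aperture.

`parse_log` accepts tab- or comma-delimited text with banner lines before
the header; column names default to common instrument headers ("Area",
"Photo", "Cond", "Trmmol", "Ci", "PhiPS2", "Label") and are fully
remappable, since log dialects vary by firmware.  `correct_log` joins
areas to rows by label (or row order, or a constant), appends `*_corr`
columns plus `AL_cm2` and `corr_factor`, preserves the original column
order, and never overwrites the source file.

## Agreement statistics

- Divergence of the width estimate from the image estimate:
  100·(wA_L − iA_L)/iA_L, signed; summarized by the maximum absolute
  value.
- Through-origin regression wA_L = b·iA_L with b = Σxy/Σx².  R² is
  reported about the mean of y: for areas clustered well away from zero
  the about-zero convention is nearly vacuous (any slope explains most of
  Σy²), whereas the mean-referenced value is informative.  Both variants
  are available (`regression_through_origin_verbose`).
- Paired t-test on the estimate pairs (scipy), two-sided, with the
  Shapiro–Wilk p on the differences reported alongside.  Zero difference
  variance yields a flagged degenerate result rather than an exception.

## Synthetic ground truth

The generator emulates linear-to-lanceolate cereal blades: width profiles
W(s) = W₀ (constant), W₀(1 − k·s/L) (linear taper) or W₀(1 − k·(s/L)²)
(lanceolate, curved margins), with four presets ordered like the field's
familiar species (maize-like 1.4 cm > barley-like 0.7 > hard-wheat-like
0.5 > soft-wheat-like 0.4 cm base width; blade lengths 18–40 cm).  The
presets are synthetic, not calibrated species data; `sample_archetype`
adds ±8% width and ±20% taper jitter.  All randomness flows through one
explicit `numpy` generator — no hidden global state.

The enclosed-area oracle integrates min(W(s), chord(s)) across the
aperture chord by composite Simpson on 20 000 panels with a
half-resolution Richardson check (≤1e−5 cm²); it shares no code with the
closed form, so their agreement on constant-width blades (tests: ≤2e−4
cm² across a 100-point width grid) is a genuine two-route check.

Rendered scenes place a mid-grey (107/255) anti-aliased leaf strip, a 10%
darker midrib, a 2 px ink ring just outside the aperture, and a 1 cm ink
bar on a white ground, with optional additive Gaussian noise (fraction of
dynamic range), deterministic per seed.  Synthetic logs draw plausible
steady-state values (P_N 2–25 µmol m⁻² s⁻¹, g_s 0.05–0.5 mol m⁻² s⁻¹,
Φ_PSII 0.4–0.8, C_i 200–350 µmol mol⁻¹) and set the instrument's Area
column to the gasket area.

What the renders do *not* emulate — specular highlights, shadows, uneven
illumination, perspective, leaf damage, midrib shadow ambiguity —
delimits what passing tests show: the pipeline's geometry, calibration
and thresholding logic are validated; robustness to difficult real-world
photography is not, and the explicit overrides exist for exactly those
cases.

## Problem sizes and determinism

The behavioural suite measures forty synthetic leaves (ten per archetype)
rendered at 150 px/cm with 2%-of-range noise; the Monte-Carlo
cross-check uses 50 random width/gasket pairs at 10⁷ samples each with a
fixed seed (at a 3-standard-error acceptance band, a fixed seed is what
makes the check deterministic); conservation identities run on 1000-point
grids and 25-row logs.  These sizes were chosen so the whole suite runs
in about a minute while keeping every estimate's sampling error an order
of magnitude below the tolerance it checks.
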