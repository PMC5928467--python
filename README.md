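# leafgasket

Leaf-area correction for gas exchange measurements in circular clamp-on
chambers, for researchers measuring photosynthesis on narrow leaves.

Portable photosynthesis systems report net photosynthesis (P\_N), stomatal
conductance (g\_s) and transpiration (E) *per unit leaf area*, and by
default assume the leaf fills the chamber gasket aperture (area A\_G; 2 cm²
for the widely used circular 6400-40 fluorometer head).  Cereal leaves —
wheat, barley, young maize — are often narrower than the aperture, so every
per-area rate is underestimated by the factor A\_L / A\_G, where A\_L is the
leaf area actually enclosed.  `leafgasket` quantifies A\_L two ways and
rescales the instrument log accordingly:

- **Width-based (wA\_L).**  A leaf of width W\_L centred in a circular
  aperture of radius r = √(A\_G/π) leaves two equal empty circle segments
  beside its margins.  With y = W\_L/2, θ = 2·arccos(y/r):

  wA\_L = A\_G − 2·(πr²·θ°/360° − y·√(r²−y²))

  One caliper measurement at the chord through the gasket centre is enough;
  the estimate is exact for parallel margins and, because W\_L is the median
  of the enclosed trapezoid, remains accurate for tapering blades.

- **Image-based (iA\_L).**  From a photograph of the leaf under a printed,
  to-scale gasket impression on white paper: pixel scale from a printed
  1 cm bar, impression circle by a Hough vote with algebraic refit, leaf
  pixels inside the aperture by Otsu thresholding with rim-ink exclusion
  and morphological cleanup.

Corrected rates are the reported rates times A\_G/A\_L (molar flux is
conserved); iWUE = P\_N/g\_s is invariant; C\_i and Φ\_PSII pass through
unchanged.  A validation module computes the agreement statistics between
the two estimators (per-leaf divergence, through-origin regression, paired
t-test), and a synthetic module generates parametric cereal-blade profiles,
rendered scenes with exact ground truth, and internally consistent
instrument logs.

## Worked example

```sh
$ leafgasket area-from-width --width-cm 1.0
1.48410 cm^2
```

A 1 cm-wide leaf centred in the 2 cm² gasket encloses 1.48410 cm², i.e.
74% of the aperture: uncorrected, P\_N and g\_s would be underestimated by
100·(2/1.48410 − 1) ≈ 35%.  The same computation from Python, applied to a
log:

```python
import leafgasket as lg

gasket = lg.GASKET_PRESETS["6400-40"]
wal = lg.width_based_area(1.0, gasket)      # wal.enclosed_area_wAL == 1.48410
rec = lg.GasExchangeRecord(assumed_area_S=2.0, photo_PN=10.0, cond_gs=0.2)
corr = lg.correct_record(rec, wal.enclosed_area_wAL)
# corr.photo_PN == 13.476, corr.cond_gs == 0.2695, corr.iWUE == 50.0 (unchanged)
```

The image route, end to end on a synthetic scene with known truth:

```sh
$ leafgasket synth scene --family lanceolate --base-width-cm 0.8 --seed 1 --out scene.png
$ leafgasket area-from-image scene.png --json
{
  "schema": 1,
  "iAL_cm2": 1.0799,
  ...
}
```

(the `scene.json` sidecar holds the generator's exact enclosed area; the
pipeline recovers it to well within 2%).  Batch correction of a log:

```sh
leafgasket correct-log log.tsv --width-file widths.csv --out corrected.tsv
leafgasket validate --pairs pairs.csv
```

## Layout

- `leafgasket.geometry` — gasket spec, circle-segment closed form, error of
  the uncorrected assumption
- `leafgasket.imaging` — scale calibration, circle location, segmentation
- `leafgasket.gas_exchange` — log parsing, per-record and batch correction
- `leafgasket.validation` — divergence, through-origin regression, paired t
- `leafgasket.synthetic` — leaf profiles, quadrature oracle, scene renderer,
  log generator
- `leafgasket.cli` — the `leafgasket` command

See `docs/methods.md` for the model, its assumptions and numerical choices.
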