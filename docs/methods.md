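# Methods

## The cold-air-pooling model

Cold-air pooling (CAP) is the nocturnal accumulation of dense, radiatively
cooled air in valley bottoms under calm, clear skies. Where it recurs, the
valley floor experiences ground frost that the slopes above escape; in the
South African sub-escarpment lowlands this inverts the usual treeline, with
frost-intolerant thicket above and frost-tolerant Karoo shrubland on the
floor. `capmap` implements a terrain-only classifier of CAP-prone ground:
no atmospheric physics is simulated, and the output is a binary
risk/no-risk map, not a frost-intensity prediction.

The classifier thresholds three DEM derivatives computed at the **valley
radius** *r*, half the ridge-to-ridge distance of the valley under study.
One radius applies per model run; multi-valley DEMs should be clipped and
run per valley. The thresholds are strict upper bounds:

| parameter | default | meaning |
|---|---|---|
| `slope_max_deg` | 10° | uppermost slope on which extreme frost was observed in the calibration valleys |
| `rank_max` | 0.30 | lower ~⅓ of the valley by windowed percentile elevation |
| `curv_max` | 0.0 | cell must sit in a depression at the valley scale |

The `lundquist` preset (30°, 50%, 0) reproduces the thresholds of the
high-elevation, high-latitude snow study the model descends from; on this
gentler terrain it systematically over-predicts (the calibrated mask is
always a cellwise subset — a monotonicity property of an AND of strict
inequalities, verified in the tests).

## Derivatives and numerical choices

**Horn slope.** The standard 3×3 weighted finite differences, converted to
degrees. Boundary rows/columns use edge replication. Any nodata cell
poisons the slope of its eight neighbours (and itself): terrain is never
fabricated under missing data. Horn's differences are exact on a linear
surface, which the plane fixtures exploit.

**Rank elevation.** For window half-width `k = round(r / cell)`, the rank
is `(cells strictly below + 0.5 × ties excluding self) / (window count − 1)`
over the self-inclusive `(2k+1)²` window, clamped to [0, 1]. Mid-rank tie
handling makes a constant raster rank 0.5 everywhere — which, together
with the strict 0.30 bound, is what keeps flat terrain out of the mask.
Windows truncate at the raster edge rather than emitting nodata (ranks are
mapped to the DEM edge); cells whose window retains fewer than 10 valid
cells — never a stricter bound than the full window size, so one-cell radii
remain usable — are nodata to avoid degenerate ranks.

**Broad-scale curvature.** The eight compass samples are snapped to the
nearest cell: cardinal offsets of `k` cells, diagonal offsets of `(k, k)`
(distance √2·k·cell), and `r = k·cell` in the denominators, so the formula
is evaluated exactly on the grid it samples. On a paraboloid
`Z = c(x² + y²)` the center-cell value has the closed form
`−(c·r/4)(1 + √2)`, used as an analytic oracle. A cell lacking any of its
eight samples (off-raster or nodata) is nodata: no extrapolation. The
printed source formula's diagonal denominator is typographically ambiguous
(`2√2·r` vs `2√(2r)`); the implementation reads it as `2·√2·r` — the only
dimensionally consistent reading, mirroring the `2r` of the cardinal term
at the √2·r diagonal sample distance — and exposes the alternative through
the `diagonal_denominator` switch for comparison.

All three derivatives are checked bit-exactly against naive per-cell
oracles (window sort; direct formula evaluation) on random DEMs, and obey
translation invariance and the elevation-scaling laws (rank invariant,
curvature ∝ s, slope θ → atan(s·tan θ)).

## Synthetic terrain

The U-valley generator reproduces the calibration-valley morphology: a
flat floor of width `floor_width_m` at elevation 0, side slopes rising by
`depth_m` over `(width_m − floor_width_m)/2` as
`Z(d) = depth · (2d/(width − floor_width))^p` clipped at the ridge height.
The exponent spans V-shaped (p = 1) to U-shaped, convex-sloped (p ≥ 2,
default 2) cross-sections. Optional seeded Gaussian noise provides
controlled perturbation for robustness checks; noise-free valleys are
bit-deterministic. The two built-in specs follow the calibration valleys
(7.5 × 3 km × 300 m and 12 × 2.5 km × 500 m, 30 m cells); the ground-truth
frost zone is the floor band, whose width is a fixture parameter (no
quantitative treeline elevation exists for the calibration valleys), kept
at ≤ 0.3 × valley width so the floor sits inside the rank threshold by
construction.

A rim of plateau terrain (default width = the valley radius) surrounds the
ridge-to-ridge extent. Without it no floor cell has a complete
curvature sample set at the valley radius — the window would fall off the
raster — and the model could not be evaluated on its own calibration
geometry. Raster dimensions are therefore `ceil(width/cell) ×
ceil(length/cell)` plus that stated margin on each side. Synthetic rasters
carry a real projected georeference (UTM 35S, the study region's zone) so
they exercise the same I/O paths as field GeoTIFFs.

What the synthetic valleys do **not** emulate: DEM sensor noise and voids,
curved or branching valley axes, tributary drainage, asymmetric
cross-sections, and any correspondence between the floor band and an
observed treeline. Passing the recovery tests therefore demonstrates
internal consistency of the derivatives-plus-thresholds pipeline on ideal
morphology, not field accuracy.

## Boundary agreement and calibration sweeps

Field validation of the original study was a visual overlay of the
predicted zones on treeline imagery. As a quantitative surrogate, the
toolkit reports: recall (fraction of a reference frost zone predicted
CAP), false-positive fraction (fraction of predicted CAP outside the
reference), and the symmetric mean nearest-boundary distance in cells.
Threshold sweeps rank candidates by `recall − false-positive fraction`,
ties broken toward stricter thresholds. The score deliberately does not
over-penalize small over-prediction rims: for site selection, predicting
frost where there is none merely forgoes a plantable site, whereas the
reverse kills plantings. These metrics and the composite score are design
choices of this package, not published values.

## Synthetic plot cohorts and the rank-sum test

The plot generator emulates the structure of the transplant-experiment
subset used to test the model: 30 frost-prone and 40 frost-free plots,
production rates log-normal with a common log-scale standard deviation σ
and a multiplicative arithmetic-mean effect (default 1.722, i.e. frost-free
production 72.2% higher). Two defaults need justification:

* **Baseline frost-prone mean 0.45 t C ha⁻¹ yr⁻¹** — a typical plot-level
  aboveground carbon accumulation rate for spekboom restoration plantings.
* **σ = 1.5** — calibrated analytically to the published marginal-
  significance regime: a reported U of 720 at n = 30/40 implies
  P(frost-free draw > frost-prone draw) = 720/1200 = 0.60, hence a
  standardized log-shift of √2·Φ⁻¹(0.60) ≈ 0.358 and
  σ = ln(1.722)/0.358 ≈ 1.5. Simulated cohorts then yield mean U ≈ 721 and
  ~30% power at α = 0.05, i.e. exactly the regime in which a single cohort
  lands near the significance boundary.

A consequence of this realistic dispersion is that the per-cohort
arithmetic percent-difference estimator is heavy-tailed: its per-cohort
spread is large and even means pooled over hundreds of cohorts move by
several points. The acceptance script therefore pools over 4,000 cohorts
(Monte Carlo s.e. ≈ 2 points on the percent difference); the test suite
checks effect recovery on the log scale, where the estimator is
well-behaved.

The published statistic pair itself (U = 720 with p = 0.046 at n = 30/40)
is not internally consistent with any standard Mann–Whitney variant
(E[U] = 600, σ_U ≈ 84.3, so U = 720 gives a two-sided normal p ≈ 0.16);
the original sidedness and tie handling are unstated. The implementation
takes no side in this: it reports both orientations of U, the sidedness
and the method used, and defaults to two-sided.

The test itself uses the exact permutation null when
`n_frost × n_free ≤ 10,000` and the pooled data are tie-free, otherwise
the normal approximation with tie and continuity corrections. The exact
path is verified against full enumeration for every group-size pair with
n₁ + n₂ ≤ 10, and its size is confirmed empirically (null rejection rate
within [0.03, 0.07] at α = 0.05 over 1,000 cohorts).

Exclusion-rule boundaries follow the published wording exactly: elevation
strictly greater than 1,200 m excludes (1,200 m exactly is retained);
ridge separation strictly greater than 8 km excludes. Plots on nodata mask
cells or outside the raster become `unknown` and are excluded from testing
rather than imputed. Browsing is consumed as a recorded flag — the original
judgement was field-based and is not re-inferred.

## I/O conventions

GeoTIFFs are single-band, row 0 northernmost, cell values at cell centers,
tiepoint at the top-left corner; float rasters use −9999 as nodata and
round-trip bit-exactly, masks are 8-bit with nodata 255. Geographic-CRS
files are refused unless an explicit ground cell size is supplied. KML
export polygonizes the mask (union of cell squares, collinear vertices
dropped), so polygon area equals cell count × cell area exactly, and
converts vertices to WGS84 with a built-in UTM inverse accurate to well
under one cell; CRSs other than UTM/WGS84 are refused rather than
approximated. Plot tables are CSV with a documented header and tolerant
column aliases; malformed rows are reported with file line numbers.

## Problem sizes

The default test suite and the acceptance script run the full pipeline on
the 7.5 × 3 km calibration-valley raster (200 × 350 cells at 30 m with its
margin, radius 50 cells), oracle comparisons on 50 × 50 random DEMs at
three radii, and 1,000–4,000 simulated plot cohorts; the whole acceptance
script completes in under a minute on one CPU.

## Known limitations

* The classifier is topographic only; it cannot rank frost severity, and
  it is uninformative in flat or very shallow terrain (by design it never
  flags flat ground).
* Thresholds are a regional calibration for the sub-escarpment lowlands
  (< 1,200 m); the high interior plateau behaves differently and would
  need its own calibration, which this package does not attempt.
* One valley radius per run; automatic per-valley radius estimation is out
  of scope.
* Curvature and (near edges) rank are undefined within one radius of the
  raster boundary; supply a DEM with a margin around the valley of
  interest.
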