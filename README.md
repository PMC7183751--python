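# capmap — cold-air-pooling frost-risk mapping for thicket restoration

Restoration of South African subtropical thicket relies on planting
cuttings of spekboom (*Portulacaria afra*), a frost-intolerant succulent
shrub. In the valleys of the sub-escarpment lowlands, nocturnal cold-air
pooling (CAP) concentrates radiative frost on flat valley floors while the
slopes above stay frost-free — so planting on a valley floor can doom a
restoration site. `capmap` maps that risk from terrain alone: it derives
three topographic characteristics from a digital elevation model (DEM) and
thresholds them into a binary frost-risk map that practitioners can use to
screen candidate sites.

## The model

For a valley with user-supplied radius *r* (half the ridge-to-ridge
distance), three rasters are derived from the DEM:

* **slope** — Horn's 3×3 finite-difference slope, in degrees;
* **rank elevation** — each cell's percentile elevation among all cells in
  the square window extending *r* in each cardinal direction (a
  valley-scale topographic position index in [0, 1]);
* **broad-scale curvature** — with *Z* the cell elevation and
  *Z*<sub>w/e/n/s</sub>, *Z*<sub>sw/ne/nw/se</sub> elevations sampled a
  distance *r* away in the eight compass directions,

  cv = ¼ { 1/(2r) [(Z − (Z_w+Z_e)/2) + (Z − (Z_n+Z_s)/2)]
  &nbsp;+ 1/(2√2·r) [(Z − (Z_sw+Z_ne)/2) + (Z − (Z_nw+Z_se)/2)] },

  negative in depressions and valleys, positive on crests.

A cell is classified **frost-prone** when all three strict inequalities
hold: slope < 10°, rank elevation < 0.30, curvature < 0. These thresholds
are the regional calibration for the sub-escarpment lowlands; the original
high-latitude snow-model thresholds (slope < 30°, rank < 50%) are available
as the `lundquist` preset and systematically over-predict frost extent in
this terrain. Because all bounds are strict, flat terrain (rank 0.5,
curvature 0) is never flagged — the model is meaningful in complex terrain
only.

The resulting mask can be exported to KML (polygonized zone boundaries in
WGS84) for visual comparison against the thicket–shrubland treeline in
virtual-globe imagery, and tested against restoration-plot productivity:
plots are filtered (in a valley, i.e. ridges within 8 km of one another;
unbrowsed; at most 1,200 m elevation), classified by the mask cell that
contains them, and per-class phytomass production (t C ha⁻¹ yr⁻¹) is
compared with a Mann–Whitney rank-sum test (exact when group sizes allow
and the data are tie-free).

A full synthetic-terrain module (planes, paraboloids, parameterized
U-valleys with known frost-prone floor bands, and simulated plot cohorts)
makes every stage testable without external data.

## Worked example

```python
import capmap

# Klipfontein-like calibration valley: 7.5 km x 3 km, 300 m deep, 30 m cells
dem, truth = capmap.make_valley_dem(capmap.KLIPFONTEIN)
derivs, mask = capmap.run_cap_model(dem, radius_m=1500.0)
print("CAP cells:", int(mask.binary.sum()))
report = capmap.boundary_agreement(mask, truth.frost_zone)
print(f"floor recall: {report.recall:.3f}  "
      f"false-positive fraction: {report.false_positive_fraction:.3f}")

records = capmap.make_plot_table(n_frost=30, n_free=40, effect=1.722, seed=1)
retained, excluded = capmap.filter_plots(records)
classified = capmap.classify_plots(retained, mask)
result = capmap.compare_production(classified)
print(f"n = {result.n_frost}/{result.n_free}  U = {result.U:.0f}  "
      f"p = {result.p_value:.3f}  frost-free mean "
      f"{result.percent_difference:+.1f}% vs frost-prone")
```

prints

```
CAP cells: 7500
floor recall: 1.000  false-positive fraction: 0.333
n = 25/35  U = 481  p = 0.522  frost-free mean +63.2% vs frost-prone
```

The model captures the entire valley-floor frost band; a third of the
predicted CAP area is an over-prediction rim on the lowest slopes, a
conservative error for site selection (it steers planting away from frost,
never into it). In the plot comparison, ten plots fall on mask cells with
no curvature sample (the raster rim) and are set aside as unknown rather
than imputed; `U` is the frost-free group's statistic and the percent
difference is relative to the frost-prone mean. Single 30/40 cohorts are
noisy — the seed shown lands well inside the distribution spanned by the
cohort simulations below.

From the shell, the same pipeline is:

```sh
capmap run --dem valley.tif --radius-m 1500 --out-raster cap.tif --out-kml cap.kml
capmap sweep --dem valley.tif --reference treeline.tif --radius-m 1500
capmap plots --mask cap.tif --plots plots.csv --out-report report.json
```

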