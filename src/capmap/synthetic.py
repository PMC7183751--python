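"""Idealized terrain and plot-cohort generators with known ground truth.

The fixtures here mirror the morphology of the Cape Fold Belt valleys in
which the frost model operates — steep convex side slopes flanking wide,
flat valley bottoms — so every downstream stage (derivatives, classifier,
plot statistics) can be exercised against analytic expectations:

* planes, on which Horn slope is exact and broad curvature vanishes;
* paraboloids, on which the curvature formula has a closed form;
* parameterized U-valleys with a known frost-prone floor band;
* synthetic restoration-plot cohorts with a controlled multiplicative
  production difference between frost classes.

The default valley emulates the Klipfontein calibration valley
(~7.5 km long, ~3 km wide, ~300 m deep at 30 m cells); the second
calibration valley (Buffels Nek, ~12 x 2.5 km, ~500 m deep) is expressible
with the same spec.  Synthetic rasters carry a fictitious but well-formed
projected georeference (UTM 35S) so they exercise the same code paths as
real GeoTIFFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .grid import DEMGrid

__all__ = [
    "SyntheticValleySpec",
    "GroundTruth",
    "make_plane",
    "make_paraboloid",
    "make_valley_dem",
    "make_plot_table",
    "KLIPFONTEIN",
    "BUFFELS_NEK",
]

#: fictitious projected georeference applied to all synthetic rasters
_SYNTH_CRS = "EPSG:32735"
_SYNTH_ORIGIN = (500000.0, 6320000.0)

#: floor cells must lie within this band above the nominal floor elevation
FLOOR_TOLERANCE_M = 1e-6


@dataclass(frozen=True)
class SyntheticValleySpec:
    """Parameters of an idealized U-shaped valley DEM.

    The valley runs along the x (east-west) axis: a flat floor of width
    ``floor_width_m`` at elevation 0, side slopes rising by ``depth_m``
    over ``(width_m - floor_width_m) / 2`` following
    ``Z(d) = depth * (2 d / (width - floor_width)) ** cross_section_exponent``
    for cross-valley distance ``d`` beyond the floor edge, clipped at
    ``depth_m``.  Exponent 1 gives a V-shaped valley; >= 2 the U-shaped,
    convex-sloped morphology of the study region.  A rim of plateau terrain
    of width ``margin_m`` (default: the valley radius, ``width_m / 2``) is
    added on every side so valley-radius windows fit around the floor.
    """

    length_m: float = 7500.0
    width_m: float = 3000.0
    depth_m: float = 300.0
    floor_width_m: float = 600.0
    cross_section_exponent: float = 2.0
    cell_size_m: float = 30.0
    noise_sd_m: float = 0.0
    seed: int = 0
    margin_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.depth_m > 0):
            raise ValueError("depth_m must be > 0")
        if not (0 < self.floor_width_m < self.width_m):
            raise ValueError("need 0 < floor_width_m < width_m")
        if not (self.cell_size_m > 0):
            raise ValueError("cell_size_m must be > 0")
        if self.cross_section_exponent < 1:
            raise ValueError("cross_section_exponent must be >= 1")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.length_m <= 0 or self.width_m <= 0:
            raise ValueError("length_m and width_m must be > 0")

    @property
    def radius_m(self) -> float:
        """Valley radius: half the ridge-to-ridge distance."""
        return self.width_m / 2.0

    @property
    def margin(self) -> float:
        return self.radius_m if self.margin_m is None else self.margin_m

    @property
    def margin_cells(self) -> int:
        return int(math.ceil(self.margin / self.cell_size_m))

    @property
    def shape(self) -> tuple[int, int]:
        """(nrows, ncols): ceil(width/cell) x ceil(length/cell) plus the
        margin cells on each side."""
        nrows = int(math.ceil(self.width_m / self.cell_size_m))
        ncols = int(math.ceil(self.length_m / self.cell_size_m))
        m = self.margin_cells
        return nrows + 2 * m, ncols + 2 * m


#: the two calibration-valley geometries
KLIPFONTEIN = SyntheticValleySpec(length_m=7500, width_m=3000, depth_m=300)
BUFFELS_NEK = SyntheticValleySpec(length_m=12000, width_m=2500, depth_m=500,
                                  floor_width_m=500)


@dataclass
class GroundTruth:
    """Known frost-prone zone of a synthetic valley.

    ``frost_zone`` is a binary raster (1 = floor band) aligned to the DEM;
    ``floor_axis`` is the polyline of the valley's lowest cells (the
    centerline), as a list of (row, col) pairs.
    """

    frost_zone: np.ndarray
    floor_axis: list[tuple[int, int]] = field(default_factory=list)


def make_plane(slope_deg: float, aspect_deg: float, nrows: int, ncols: int,
               cell_size_m: float) -> DEMGrid:
    """Plane DEM: elevation an exact linear function of (x, y).

    ``aspect_deg`` is the downslope compass direction (0 = north,
    90 = east), so the elevation gradient points the opposite way with
    magnitude ``tan(slope_deg)``.
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("nrows and ncols must be positive")
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be > 0")
    if not (0 <= slope_deg < 90):
        raise ValueError("slope_deg must be in [0, 90)")
    g = math.tan(math.radians(slope_deg))
    az = math.radians(aspect_deg)
    # unit downslope vector in (east, north) components; snap the residue
    # of cardinal aspects (cos 270 deg ~ -1.8e-16) so planes are exactly
    # constant along the contour direction
    ux, uy = math.sin(az), math.cos(az)
    ux = 0.0 if abs(ux) < 1e-12 else ux
    uy = 0.0 if abs(uy) < 1e-12 else uy
    cols = np.arange(ncols) * cell_size_m
    rows = np.arange(nrows) * cell_size_m
    x = cols[None, :]
    y = -rows[:, None]  # row 0 is northernmost
    z = -g * (ux * x + uy * y)
    z = z - z.min()
    return DEMGrid(np.broadcast_to(z, (nrows, ncols)).copy(), cell_size_m,
                   _SYNTH_ORIGIN, _SYNTH_CRS)


def make_paraboloid(c: float, nrows: int, ncols: int,
                    cell_size_m: float) -> DEMGrid:
    """Paraboloid DEM, Z(x, y) = c * (x^2 + y^2) about the grid center.

    ``c > 0`` is a bowl (negative broad curvature at the center), ``c < 0``
    a dome.  The center is the cell at (nrows // 2, ncols // 2).
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("nrows and ncols must be positive")
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be > 0")
    if not np.isfinite(c):
        raise ValueError("c must be finite")
    r0, c0 = nrows // 2, ncols // 2
    y = (np.arange(nrows)[:, None] - r0) * cell_size_m
    x = (np.arange(ncols)[None, :] - c0) * cell_size_m
    z = c * (x * x + y * y)
    return DEMGrid(z, cell_size_m, _SYNTH_ORIGIN, _SYNTH_CRS)


def make_valley_dem(spec: SyntheticValleySpec) -> tuple[DEMGrid, GroundTruth]:
    """U-shaped valley DEM with its ground-truth frost-prone floor band.

    Deterministic for a fixed spec (the Gaussian noise is seeded); with
    ``noise_sd_m = 0`` every floor cell sits at elevation exactly 0.
    """
    nrows, ncols = spec.shape
    m = spec.margin_cells
    cell = spec.cell_size_m
    width_rows = int(math.ceil(spec.width_m / cell))
    # cross-valley distance of each row's cell center from the valley axis
    y_center = (m + width_rows / 2.0) * cell
    y = (np.arange(nrows) + 0.5) * cell
    d_axis = np.abs(y - y_center)
    half_floor = spec.floor_width_m / 2.0
    half_slope = (spec.width_m - spec.floor_width_m) / 2.0
    d = np.clip(d_axis - half_floor, 0.0, None)
    profile = spec.depth_m * np.minimum(d / half_slope, 1.0) ** spec.cross_section_exponent
    z = np.broadcast_to(profile[:, None], (nrows, ncols)).copy()

    if spec.noise_sd_m > 0:
        rng = np.random.default_rng(spec.seed)
        z = z + rng.normal(0.0, spec.noise_sd_m, size=z.shape)

    dem = DEMGrid(z, cell, _SYNTH_ORIGIN, _SYNTH_CRS)
    floor_rows = d_axis <= half_floor
    frost = np.zeros((nrows, ncols), dtype=np.uint8)
    frost[floor_rows, :] = 1
    axis_row = int(np.argmin(d_axis))
    axis = [(axis_row, j) for j in range(ncols)]
    return dem, GroundTruth(frost_zone=frost, floor_axis=axis)


# ---------------------------------------------------------------------------
# synthetic restoration-plot cohorts


@lru_cache(maxsize=4)
def _default_valley(spec: SyntheticValleySpec = KLIPFONTEIN):
    return make_valley_dem(spec)


@lru_cache(maxsize=4)
def _plot_site_pools(spec: SyntheticValleySpec):
    """Candidate (row, col) pools for frost-prone (floor) and frost-free
    (interior side-slope) plot sites on the reference valley."""
    dem, truth = _default_valley(spec)
    nrows, ncols = dem.shape
    m = spec.margin_cells
    frost_cells = np.argwhere(truth.frost_zone == 1)
    rows = np.arange(nrows)
    floor_rows = np.any(truth.frost_zone == 1, axis=1)
    slope_rows = (rows >= m) & (rows < nrows - m) & ~floor_rows
    rr, cc = np.meshgrid(rows[slope_rows], np.arange(m, ncols - m),
                         indexing="ij")
    free_cells = np.column_stack([rr.ravel(), cc.ravel()])
    return dem, frost_cells, free_cells


def make_plot_table(n_frost: int, n_free: int, effect: float = 1.722,
                    frost_mean: float = 0.45, noise_sd_log: float = 1.5,
                    seed: int = 0,
                    valley_spec: SyntheticValleySpec = KLIPFONTEIN):
    """Synthetic restoration-plot cohort on a reference valley.

    Production rates (t C ha^-1 yr^-1) are log-normal with the frost-free
    arithmetic mean ``effect`` times the frost-prone mean and a common
    log-scale standard deviation ``noise_sd_log``.  Frost-prone plots are
    placed on floor-band cells of the reference valley, frost-free plots on
    the side slopes above the floor; records carry the exclusion metadata
    (browsing flag, ridge separation, elevation) and their construction
    frost class.

    Returns a list of :class:`capmap.plots.PlotRecord`.
    """
    from .plots import FROST_FREE, FROST_PRONE, PlotRecord

    if n_frost < 0 or n_free < 0:
        raise ValueError("group sizes must be >= 0")
    if not (effect > 0):
        raise ValueError("effect must be > 0")
    rng = np.random.default_rng(seed)
    dem, frost_cells, free_cells = _plot_site_pools(valley_spec)

    def sample_cells(cells: np.ndarray, n: int) -> np.ndarray:
        idx = rng.choice(len(cells), size=n, replace=n > len(cells))
        return cells[idx]

    # log-normal means: E = exp(mu + s^2/2)
    s = noise_sd_log
    mu_frost = math.log(frost_mean) - s * s / 2.0
    mu_free = math.log(frost_mean * effect) - s * s / 2.0

    records = []
    for klass, n, mu, cells in (
            (FROST_PRONE, n_frost, mu_frost, frost_cells),
            (FROST_FREE, n_free, mu_free, free_cells)):
        if n == 0:
            continue
        chosen = sample_cells(cells, n)
        prod = rng.lognormal(mean=mu, sigma=s, size=n)
        for (r, c), p in zip(chosen, prod):
            x, y = dem.cell_center(int(r), int(c))
            records.append(PlotRecord(
                plot_id=f"TWP{len(records) + 1:03d}",
                x=x, y=y,
                elevation_m=float(dem.elevations[int(r), int(c)]),
                production_tC_ha_yr=float(p),
                browsed=False,
                ridge_separation_km=valley_spec.width_m / 1000.0,
                in_valley=True,
                frost_class=klass,
            ))
    return records
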