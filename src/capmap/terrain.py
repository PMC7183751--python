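"""Topographic derivatives thresholded by the cold-air-pooling model.

Three rasters are derived from a DEM:

* **Horn slope** — steepness in degrees from Horn's 3x3 weighted finite
  differences.
* **Rank elevation** — the percentile elevation of each cell among all
  cells of a square window whose half-width is the valley radius, i.e. a
  valley-scale topographic position index in [0, 1].
* **Broad-scale curvature** — a signed finite-difference measure sampling
  elevation a full valley radius away in the eight compass directions;
  negative in depressions and valleys, positive on crests.

The rank and curvature windows share one user-supplied valley radius,
defined as half the ridge-to-ridge distance of the valley under study, so
both derivatives describe a cell's position in the *valley-scale* landscape
rather than among its immediate neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DEMGrid

__all__ = [
    "TerrainDerivatives",
    "horn_slope",
    "rank_elevation",
    "broad_curvature",
    "compute_derivatives",
]

#: a rank is only emitted when at least this many window cells are valid
MIN_RANK_WINDOW_CELLS = 10


@dataclass
class TerrainDerivatives:
    """Slope, rank-elevation and curvature rasters aligned to one DEM."""

    slope_deg: DEMGrid
    rank_elev: DEMGrid
    curvature: DEMGrid
    radius_m: float

    def __post_init__(self) -> None:
        if not (self.slope_deg.aligned_with(self.rank_elev)
                and self.slope_deg.aligned_with(self.curvature)):
            raise ValueError("derivative rasters are not mutually aligned")


def _radius_cells(radius_m: float, cell_size_m: float) -> int:
    """Radius in whole cells: round to nearest, minimum 1."""
    if radius_m < cell_size_m:
        raise ValueError(
            f"radius_m={radius_m} is smaller than one cell ({cell_size_m} m)")
    return max(1, int(round(radius_m / cell_size_m)))


def horn_slope(dem: DEMGrid) -> DEMGrid:
    """Slope in degrees by Horn's 3x3 weighted finite differences.

    Boundary rows/columns are handled by edge replication.  A cell whose
    3x3 neighbourhood touches any nodata cell becomes nodata: terrain is
    never fabricated under missing data.

    Raises
    ------
    ValueError
        If the raster is smaller than 3x3 or contains no valid cell.
    """
    nrows, ncols = dem.shape
    if nrows < 3 or ncols < 3:
        raise ValueError("horn_slope needs at least a 3x3 raster")
    if dem.n_valid == 0:
        raise ValueError("horn_slope: input raster is entirely nodata")

    z = np.pad(dem.elevations, 1, mode="edge")
    bad = np.pad(dem.nodata_mask, 1, mode="edge")

    # Horn 1981 kernel: dz/dx weighs the east/west columns 1-2-1.
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dem.cell_size_m)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dem.cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    invalid = np.zeros(dem.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            invalid |= bad[1 + dr: 1 + dr + nrows, 1 + dc: 1 + dc + ncols]
    slope[invalid] = np.nan
    return DEMGrid(slope, dem.cell_size_m, dem.origin, dem.crs_tag)


def rank_elevation(dem: DEMGrid, radius_m: float) -> DEMGrid:
    """Valley-scale percentile elevation of each cell in [0, 1].

    For each valid cell the window is the (2k+1) x (2k+1) square of cells
    within ``k = round(radius_m / cell_size_m)`` cells in each cardinal
    direction, self-inclusive and truncated at the raster edge.  The rank is

        (count strictly below + 0.5 * count tied, self excluded)
        / (valid window count - 1)

    so a constant raster ranks 0.5 everywhere (mid-rank tie convention).
    Cells with fewer than ``MIN_RANK_WINDOW_CELLS`` valid window cells, and
    nodata cells, are nodata in the output.
    """
    k = _radius_cells(radius_m, dem.cell_size_m)
    z = dem.elevations
    valid = ~dem.nodata_mask
    nrows, ncols = dem.shape

    below = np.zeros(dem.shape, dtype=np.int64)
    tied = np.zeros(dem.shape, dtype=np.int64)   # includes self
    count = np.zeros(dem.shape, dtype=np.int64)  # includes self

    # accumulate over window offsets: each offset contributes one shifted
    # comparison of the whole raster against itself
    for dr in range(-k, k + 1):
        r_src = slice(max(0, dr), min(nrows, nrows + dr))
        r_dst = slice(max(0, -dr), min(nrows, nrows - dr))
        for dc in range(-k, k + 1):
            c_src = slice(max(0, dc), min(ncols, ncols + dc))
            c_dst = slice(max(0, -dc), min(ncols, ncols - dc))
            zs = z[r_src, c_src]
            vs = valid[r_src, c_src]
            zc = z[r_dst, c_dst]
            below[r_dst, c_dst] += (zs < zc) & vs
            tied[r_dst, c_dst] += (zs == zc) & vs
            count[r_dst, c_dst] += vs

    with np.errstate(invalid="ignore", divide="ignore"):
        rank = (below + 0.5 * (tied - 1)) / (count - 1)
    rank = np.clip(rank, 0.0, 1.0)
    rank[~valid] = np.nan
    # degenerate-window guard (edge truncation / nodata holes); never
    # stricter than the full window size so small radii stay usable
    rank[count < min(MIN_RANK_WINDOW_CELLS, (2 * k + 1) ** 2)] = np.nan
    return DEMGrid(rank, dem.cell_size_m, dem.origin, dem.crs_tag)


def _shift(z: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Raster translated by (dr, dc) cells, nan-padded outside the extent."""
    nrows, ncols = z.shape
    out = np.full_like(z, np.nan)
    r_src = slice(max(0, dr), min(nrows, nrows + dr))
    r_dst = slice(max(0, -dr), min(nrows, nrows - dr))
    c_src = slice(max(0, dc), min(ncols, ncols + dc))
    c_dst = slice(max(0, -dc), min(ncols, ncols - dc))
    out[r_dst, c_dst] = z[r_src, c_src]
    return out


def broad_curvature(dem: DEMGrid, radius_m: float,
                    diagonal_denominator: str = "sqrt2_r") -> DEMGrid:
    """Broad-scale curvature at the valley radius.

    With Z the cell elevation and Z_w/e/n/s, Z_sw/ne/nw/se the elevations
    sampled a distance r away in the eight compass directions::

        cv = 1/4 * { 1/(2r)       * [(Z - (Zw+Ze)/2) + (Z - (Zn+Zs)/2)]
                   + 1/(2*sqrt2*r) * [(Z - (Zsw+Zne)/2) + (Z - (Znw+Zse)/2)] }

    Samples snap to the nearest cell: the cardinal offset is
    ``k = round(r / cell_size)`` cells and diagonals sit at ``(k, k)``,
    a distance sqrt(2)*k*cell away, so ``r`` in the denominators is the
    snapped distance ``k * cell_size``.  Depressions give cv < 0, crests
    cv > 0.  Cells whose eight sample points do not all fall on valid
    in-extent cells are nodata.

    ``diagonal_denominator`` selects the reading of the diagonal weight:
    ``"sqrt2_r"`` (default) uses 2*sqrt(2)*r, matching the sqrt(2)*r
    diagonal sample distance; ``"sqrt_2r"`` uses 2*sqrt(2*r).
    """
    if diagonal_denominator not in ("sqrt2_r", "sqrt_2r"):
        raise ValueError(f"unknown diagonal_denominator {diagonal_denominator!r}")
    k = _radius_cells(radius_m, dem.cell_size_m)
    r = k * dem.cell_size_m
    z = dem.elevations.copy()
    z[dem.nodata_mask] = np.nan

    # _shift(z, dr, dc)[i, j] == z[i+dr, j+dc]; row 0 is north
    zw, ze = _shift(z, 0, -k), _shift(z, 0, k)
    zn, zs = _shift(z, -k, 0), _shift(z, k, 0)
    znw, zse = _shift(z, -k, -k), _shift(z, k, k)
    zne, zsw = _shift(z, -k, k), _shift(z, k, -k)

    diag_den = 2.0 * np.sqrt(2.0) * r if diagonal_denominator == "sqrt2_r" \
        else 2.0 * np.sqrt(2.0 * r)
    cv = 0.25 * (
        ((z - (zw + ze) / 2.0) + (z - (zn + zs) / 2.0)) / (2.0 * r)
        + ((z - (zsw + zne) / 2.0) + (z - (znw + zse) / 2.0)) / diag_den
    )
    if not np.any(np.isfinite(cv)):
        import warnings
        warnings.warn(
            f"broad_curvature: radius {radius_m} m leaves no cell with a "
            "complete sample set; result is entirely nodata", stacklevel=2)
    return DEMGrid(cv, dem.cell_size_m, dem.origin, dem.crs_tag)


def compute_derivatives(dem: DEMGrid, radius_m: float,
                        diagonal_denominator: str = "sqrt2_r",
                        ) -> TerrainDerivatives:
    """All three derivatives for one DEM and one valley radius."""
    return TerrainDerivatives(
        slope_deg=horn_slope(dem),
        rank_elev=rank_elevation(dem, radius_m),
        curvature=broad_curvature(dem, radius_m, diagonal_denominator),
        radius_m=float(radius_m),
    )
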