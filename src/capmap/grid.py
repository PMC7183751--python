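"""Raster grid container used throughout the toolkit.

A :class:`DEMGrid` is a single-band elevation raster on a square-celled,
projected grid with meter units.  Row 0 is the northernmost row and cell
values refer to cell centers; the stored origin is the projected coordinate
of the raster's top-left (north-west) *corner*.  Elevations are float64 with
``nan`` at nodata cells; the boolean ``nodata_mask`` is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DEMGrid"]


@dataclass
class DEMGrid:
    """Rectangular elevation raster.

    Parameters
    ----------
    elevations : ndarray of float, shape (nrows, ncols)
        Elevation in meters; ``nan`` marks nodata.
    cell_size_m : float
        Square cell edge length in meters (> 0).
    origin : tuple of float
        Projected ``(x, y)`` of the top-left corner of the raster.
    crs_tag : str
        Opaque CRS identifier, e.g. ``"EPSG:32735"``.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no elevation.  Derived from the nan
        pattern of ``elevations`` when omitted.
    """

    elevations: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "EPSG:32735"
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=np.float64)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be a 2-D array")
        if self.elevations.size == 0:
            raise ValueError("elevations must be non-empty")
        if not (self.cell_size_m > 0):
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")
        if self.nodata_mask is None:
            self.nodata_mask = np.isnan(self.elevations)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.elevations.shape:
                raise ValueError("nodata_mask shape does not match elevations")
            self.elevations = self.elevations.copy()
            self.elevations[self.nodata_mask] = np.nan
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of the center of cell ``(row, col)``."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size_m,
                y0 - (row + 0.5) * self.cell_size_m)

    def cell_at(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell containing projected point ``(x, y)``.

        Returns None when the point falls outside the raster extent.
        """
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size_m))
        row = int(np.floor((y0 - y) / self.cell_size_m))
        nrows, ncols = self.shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def aligned_with(self, other: "DEMGrid", tol: float = 1e-6) -> bool:
        """True when the two grids share shape, cell size and origin."""
        return (self.shape == other.shape
                and abs(self.cell_size_m - other.cell_size_m) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)

    def with_elevations(self, elevations: np.ndarray) -> "DEMGrid":
        """New grid with the same georeference but different values."""
        return replace(self, elevations=np.asarray(elevations, dtype=np.float64),
                       nodata_mask=None)
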