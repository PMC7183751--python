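"""GeoTIFF, KML and plot-table input/output.

Rasters are single-band GeoTIFFs with explicit georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKey directory carrying the
EPSG code, and the GDAL nodata convention).  Row 0 is the northernmost row,
cell values refer to cell centers, and the tiepoint anchors the raster's
top-left corner — the dominant GeoTIFF convention, stated here to rule out
silent half-cell shifts.  Float rasters round-trip bit-exactly.

CAP masks are exported to KML as polygonized vectors (boundary traces of
the connected CAP zones converted to WGS84 lon/lat), so the prediction can
be overlaid at any zoom on virtual-globe imagery and compared against
observed treelines.

Plot tables are comma-separated text.  Documented header (order free,
extra columns preserved but ignored)::

    plot_id,x,y,elevation_m,production_tC_ha_yr,browsed,
    ridge_separation_km[,in_valley][,frost_class]

``browsed`` and ``in_valley`` accept 0/1/true/false/yes/no; at least one of
``ridge_separation_km`` / ``in_valley`` must be present (valley-context
metadata); ``frost_class`` is optional and, when present, takes precedence
over raster sampling if the caller says so.  Accepted aliases:
``browsed_flag`` for ``browsed``, ``production`` for the production column,
``lon``/``lat`` for ``x``/``y`` (converted given a projected CRS).
"""

from __future__ import annotations

import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from . import geo
from .classify import MASK_NODATA, CAPMask
from .grid import DEMGrid

__all__ = [
    "RasterMetadata",
    "read_dem",
    "read_cap_mask",
    "write_raster",
    "polygonize_mask",
    "export_kml",
    "read_plot_table",
    "write_plot_table",
    "PlotTableError",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024      # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025     # 1 = PixelIsArea
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072

FLOAT_NODATA = -9999.0


class PlotTableError(ValueError):
    """Plot table does not conform to the documented schema."""


@dataclass
class RasterMetadata:
    """Georeferencing read from or written to a GeoTIFF."""

    nrows: int
    ncols: int
    cell_size_m: float
    origin: tuple[float, float]
    crs_tag: str
    nodata: float
    geographic: bool = False


def _epsg_code(crs_tag: str) -> int:
    tag = crs_tag.strip().upper()
    if not tag.startswith("EPSG:"):
        raise ValueError(f"crs_tag must be 'EPSG:<code>', got {crs_tag!r}")
    return int(tag.split(":", 1)[1])


def _geokeys(crs_tag: str) -> tuple[int, ...]:
    code = _epsg_code(crs_tag)
    geographic = code == 4326
    model = 2 if geographic else 1
    cs_key = _KEY_GEOGRAPHIC_CS if geographic else _KEY_PROJECTED_CS
    # header: version, revision, minor, number of keys; then 3 keys
    return (1, 1, 0, 3,
            _KEY_MODEL_TYPE, 0, 1, model,
            _KEY_RASTER_TYPE, 0, 1, 1,
            cs_key, 0, 1, code)


def write_raster(grid: DEMGrid | CAPMask, path: str | os.PathLike) -> str:
    """Write a grid or CAP mask as a single-band GeoTIFF.

    Float grids are written float64 with nodata ``FLOAT_NODATA``; masks are
    8-bit with nodata 255.  Round-trips through :func:`read_dem` /
    :func:`read_cap_mask` are bit-exact on valid cells.
    """
    if isinstance(grid, CAPMask):
        data = grid.mask
        nodata: float = MASK_NODATA
        cell, origin, crs = grid.cell_size_m, grid.origin, grid.crs_tag
    elif isinstance(grid, DEMGrid):
        data = grid.elevations.copy()
        data[grid.nodata_mask] = FLOAT_NODATA
        nodata = FLOAT_NODATA
        cell, origin, crs = grid.cell_size_m, grid.origin, grid.crs_tag
    else:
        raise TypeError(f"cannot write {type(grid).__name__} as a raster")
    if data.size == 0:
        raise ValueError("refusing to write an empty raster")

    keys = _geokeys(crs)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(cell), float(cell), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
        (_TAG_GEO_KEYS, "H", len(keys), keys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))
         if not float(nodata).is_integer() else str(int(nodata))),
    ]
    tifffile.imwrite(os.fspath(path), data, extratags=extratags)
    return os.fspath(path)


def _read_metadata(page: "tifffile.TiffPage") -> RasterMetadata:
    tags = page.tags
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError("raster lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
    tie = tags[_TAG_TIEPOINT].value
    i, j = tie[0], tie[1]
    origin = (float(tie[3] - j * sx), float(tie[4] + i * sy))
    if not math.isclose(sx, sy, rel_tol=1e-6):
        raise ValueError(f"cells are not square ({sx} x {sy})")

    crs_tag, geographic = "unknown", False
    if _TAG_GEO_KEYS in tags:
        keys = tuple(tags[_TAG_GEO_KEYS].value)
        entries = {keys[n]: keys[n + 3] for n in range(4, len(keys), 4)}
        geographic = entries.get(_KEY_MODEL_TYPE) == 2
        code = entries.get(_KEY_GEOGRAPHIC_CS if geographic
                           else _KEY_PROJECTED_CS)
        if code:
            crs_tag = f"EPSG:{code}"

    nodata = math.nan
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    return RasterMetadata(page.imagelength, page.imagewidth, float(sx),
                          origin, crs_tag, nodata, geographic)


def _read_band(path: str | os.PathLike, band: int | None):
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(os.fspath(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        meta = _read_metadata(page)
    if data.ndim == 3:
        if band is None:
            raise ValueError(
                f"{path} has {data.shape[-1] if data.shape[-1] < data.shape[0] else data.shape[0]}"
                " bands; select one with band=<index>")
        data = data[band] if data.shape[0] < data.shape[-1] else data[..., band]
    return np.asarray(data), meta


def read_dem(path: str | os.PathLike, band: int | None = None,
             meters_per_cell: float | None = None) -> DEMGrid:
    """Read a single-band elevation GeoTIFF into a :class:`DEMGrid`.

    The file must be in a projected CRS with meter units.  A geographic-CRS
    file is refused unless ``meters_per_cell`` supplies an explicit ground
    cell size, in which case cell centers keep their stored coordinates but
    derivative windows use the override.
    """
    data, meta = _read_band(path, band)
    if meta.geographic and meters_per_cell is None:
        raise ValueError(
            f"{path} is in a geographic CRS ({meta.crs_tag}): cell size is "
            "in degrees, not meters. Either reproject the DEM or pass "
            "meters_per_cell=<ground cell size in m> to override.")
    cell = meters_per_cell if meters_per_cell is not None else meta.cell_size_m
    z = data.astype(np.float64)
    if not math.isnan(meta.nodata):
        z[data == meta.nodata] = np.nan
    return DEMGrid(z, cell, meta.origin, meta.crs_tag)


def read_cap_mask(path: str | os.PathLike) -> CAPMask:
    """Read an 8-bit CAP mask GeoTIFF written by :func:`write_raster`."""
    data, meta = _read_band(path, None)
    return CAPMask(data.astype(np.uint8), meta.cell_size_m, meta.origin,
                   meta.crs_tag)


# ---------------------------------------------------------------------------
# KML export

_KML_NS = "http://www.opengis.net/kml/2.2"


def polygonize_mask(mask: CAPMask):
    """Connected CAP zones as shapely polygons in projected coordinates.

    Each polygon is the exact union of the CAP cells' squares, so its area
    equals cell count x cell area.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    cell = mask.cell_size_m
    x0, y0 = mask.origin
    rows, cols = np.nonzero(mask.binary)
    boxes = [box(x0 + c * cell, y0 - (r + 1) * cell,
                 x0 + (c + 1) * cell, y0 - r * cell)
             for r, c in zip(rows, cols)]
    if not boxes:
        return []
    merged = unary_union(boxes).simplify(0)  # drop collinear edge vertices
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)


def _ring_coords(ring, crs_tag: str) -> str:
    xs, ys = zip(*ring.coords)
    lon, lat = geo.to_lonlat(crs_tag, np.array(xs), np.array(ys))
    return " ".join(f"{lo:.8f},{la:.8f},0" for lo, la in zip(lon, lat))


def export_kml(mask: CAPMask, path: str | os.PathLike,
               name: str = "CAP frost-risk zones") -> str:
    """Write the polygonized CAP zones as a KML overlay in WGS84.

    Raises ``ValueError`` when the mask CRS has no supported geographic
    conversion.  An all-zero mask yields a valid KML with no polygons.
    """
    if not geo.supports_lonlat(mask.crs_tag):
        raise ValueError(
            f"cannot export KML: CRS {mask.crs_tag!r} has no geographic "
            "conversion")
    ET.register_namespace("", _KML_NS)
    kml = ET.Element(f"{{{_KML_NS}}}kml")
    doc = ET.SubElement(kml, f"{{{_KML_NS}}}Document")
    ET.SubElement(doc, f"{{{_KML_NS}}}name").text = name
    style = ET.SubElement(doc, f"{{{_KML_NS}}}Style", id="cap")
    poly_style = ET.SubElement(style, f"{{{_KML_NS}}}PolyStyle")
    ET.SubElement(poly_style, f"{{{_KML_NS}}}color").text = "7f0000ff"
    ET.SubElement(poly_style, f"{{{_KML_NS}}}outline").text = "1"

    for k, poly in enumerate(polygonize_mask(mask), start=1):
        pm = ET.SubElement(doc, f"{{{_KML_NS}}}Placemark")
        ET.SubElement(pm, f"{{{_KML_NS}}}name").text = f"CAP zone {k}"
        ET.SubElement(pm, f"{{{_KML_NS}}}styleUrl").text = "#cap"
        pe = ET.SubElement(pm, f"{{{_KML_NS}}}Polygon")
        ob = ET.SubElement(pe, f"{{{_KML_NS}}}outerBoundaryIs")
        ring = ET.SubElement(ob, f"{{{_KML_NS}}}LinearRing")
        ET.SubElement(ring, f"{{{_KML_NS}}}coordinates").text = \
            _ring_coords(poly.exterior, mask.crs_tag)
        for interior in poly.interiors:
            ib = ET.SubElement(pe, f"{{{_KML_NS}}}innerBoundaryIs")
            iring = ET.SubElement(ib, f"{{{_KML_NS}}}LinearRing")
            ET.SubElement(iring, f"{{{_KML_NS}}}coordinates").text = \
                _ring_coords(interior, mask.crs_tag)

    ET.ElementTree(kml).write(os.fspath(path), xml_declaration=True,
                              encoding="utf-8")
    return os.fspath(path)


# ---------------------------------------------------------------------------
# plot tables

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}

_COLUMN_ALIASES = {
    "browsed_flag": "browsed",
    "production": "production_tC_ha_yr",
    "production_tc_ha_yr": "production_tC_ha_yr",
    "elevation": "elevation_m",
}
_MANDATORY = ("plot_id", "x", "y", "elevation_m", "production_tC_ha_yr",
              "browsed")


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"line {line}: column {column!r} has non-boolean "
                     f"value {value!r}")


def read_plot_table(path: str | os.PathLike, crs_tag: str | None = None,
                    lonlat: bool = False, on_error: str = "raise"):
    """Read a restoration-plot table (CSV) into PlotRecords.

    With ``lonlat=True`` the coordinate columns (``lon``/``lat`` or
    ``x``/``y``) are interpreted as WGS84 degrees and converted into the
    projected CRS ``crs_tag``.  Malformed rows (negative production,
    unparseable booleans or numbers) are reported with their file line
    numbers; ``on_error="raise"`` (default) raises a single error listing
    them all, ``on_error="skip"`` drops them and returns
    ``(records, problems)``.
    """
    from .plots import FROST_CLASSES, UNKNOWN, PlotRecord

    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    canonical = {"production_tC_ha_yr": "production_tC_ha_yr"}
    canonical.update({c: c for c in ("plot_id", "x", "y", "elevation_m",
                                     "browsed", "ridge_separation_km",
                                     "in_valley", "frost_class",
                                     "lon", "lat")})
    canonical.update({k.lower(): v for k, v in canonical.items()})

    def _norm(col: str) -> str:
        low = col.strip().lower()
        low = _COLUMN_ALIASES.get(low, low)
        return canonical.get(low, col.strip())

    df.columns = [_norm(c) for c in df.columns]
    if lonlat and "lon" in df.columns and "lat" in df.columns:
        df = df.rename(columns={"lon": "x", "lat": "y"})

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise PlotTableError(
            f"{path}: missing mandatory column(s) {missing}; documented "
            "header: plot_id,x,y,elevation_m,production_tC_ha_yr,browsed,"
            "ridge_separation_km[,in_valley][,frost_class]")
    if "ridge_separation_km" not in df.columns and \
            "in_valley" not in df.columns:
        raise PlotTableError(
            f"{path}: need valley-context metadata — either "
            "'ridge_separation_km' or 'in_valley'")

    records, problems = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            x, y = float(row["x"]), float(row["y"])
            if lonlat:
                if crs_tag is None:
                    raise ValueError(
                        f"line {line}: lonlat coordinates need a target "
                        "crs_tag")
                x, y = (float(v) for v in geo.from_lonlat(crs_tag, x, y))
            production = float(row["production_tC_ha_yr"])
            if production < 0:
                raise ValueError(
                    f"line {line}: negative production rate {production}")
            ridge = row.get("ridge_separation_km")
            ridge_km = float(ridge) if ridge not in (None, "") \
                and not pd.isna(ridge) else math.nan
            in_valley = None
            if "in_valley" in df.columns and not pd.isna(row["in_valley"]):
                in_valley = _parse_bool(row["in_valley"], line, "in_valley")
            frost = UNKNOWN
            if "frost_class" in df.columns and not pd.isna(row["frost_class"]):
                frost = str(row["frost_class"]).strip()
                if frost not in FROST_CLASSES:
                    raise ValueError(
                        f"line {line}: frost_class {frost!r} not one of "
                        f"{sorted(FROST_CLASSES)}")
            records.append(PlotRecord(
                plot_id=str(row["plot_id"]).strip(),
                x=x, y=y,
                elevation_m=float(row["elevation_m"]),
                production_tC_ha_yr=production,
                browsed=_parse_bool(row["browsed"], line, "browsed"),
                ridge_separation_km=ridge_km,
                in_valley=in_valley,
                frost_class=frost,
            ))
        except (ValueError, TypeError) as exc:
            problems.append((line, str(exc)))
    if problems and on_error == "raise":
        detail = "; ".join(msg for _, msg in problems)
        raise ValueError(f"{path}: {len(problems)} malformed row(s): {detail}")
    return (records, problems) if on_error == "skip" else records


def write_plot_table(records, path: str | os.PathLike) -> str:
    """Write PlotRecords as CSV with the documented header."""
    rows = [{
        "plot_id": r.plot_id, "x": r.x, "y": r.y,
        "elevation_m": r.elevation_m,
        "production_tC_ha_yr": r.production_tC_ha_yr,
        "browsed": int(r.browsed),
        "ridge_separation_km": r.ridge_separation_km,
        "in_valley": "" if r.in_valley is None else int(r.in_valley),
        "frost_class": r.frost_class,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
    return os.fspath(path)
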