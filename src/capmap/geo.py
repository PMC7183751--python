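"""Point coordinate conversion from projected CRS to geographic (WGS84).

Only what virtual-globe export needs: the inverse Transverse Mercator
mapping for UTM zones (EPSG:326xx north / 327xx south) on the WGS84
ellipsoid, by the standard footpoint-latitude series (Snyder 1987,
eqs. 8-17..8-25), accurate to well under a meter — far below one DEM cell.
EPSG:4326 passes through unchanged.  This is deliberately not a general
reprojection engine.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["to_lonlat", "from_lonlat", "supports_lonlat"]

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996

_UTM_RE = re.compile(r"^EPSG:(32[67])(\d{2})$", re.IGNORECASE)


def _parse_utm(crs_tag: str) -> tuple[int, bool] | None:
    m = _UTM_RE.match(crs_tag.strip())
    if not m:
        return None
    zone = int(m.group(2))
    if not 1 <= zone <= 60:
        return None
    return zone, m.group(1) == "327"


def supports_lonlat(crs_tag: str) -> bool:
    """True when :func:`to_lonlat` can convert this CRS."""
    tag = crs_tag.strip().upper()
    return tag == "EPSG:4326" or _parse_utm(tag) is not None


def to_lonlat(crs_tag: str, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Convert projected ``(x, y)`` (meters) to (longitude, latitude) degrees.

    Raises ``ValueError`` for CRS tags with no supported geographic
    conversion.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    tag = crs_tag.strip().upper()
    if tag == "EPSG:4326":
        return x, y
    parsed = _parse_utm(tag)
    if parsed is None:
        raise ValueError(
            f"no geographic conversion available for CRS {crs_tag!r}; "
            "supported: EPSG:4326 and UTM zones EPSG:326xx / EPSG:327xx")
    zone, south = parsed
    lon0 = np.radians(-183.0 + 6.0 * zone)

    xm = x - 500000.0
    ym = y - 10000000.0 if south else y

    m = ym / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
    phi1 = (mu
            + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
            + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
            + (151 * e1**3 / 96) * np.sin(6 * mu)
            + (1097 * e1**4 / 512) * np.sin(8 * mu))

    sin1, cos1 = np.sin(phi1), np.cos(phi1)
    tan1 = sin1 / cos1
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / np.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    d = xm / (n1 * _K0)

    lat = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2
           - 3 * c1**2) * d**6 / 720)
    lon = lon0 + (
        d - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2
           + 24 * t1**2) * d**5 / 120) / cos1
    return np.degrees(lon), np.degrees(lat)


def from_lonlat(crs_tag: str, lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Convert (longitude, latitude) degrees to projected ``(x, y)`` meters.

    Inverse companion of :func:`to_lonlat`; same CRS support.
    """
    lon = np.asarray(lon, dtype=np.float64)
    lat = np.asarray(lat, dtype=np.float64)
    tag = crs_tag.strip().upper()
    if tag == "EPSG:4326":
        return lon, lat
    parsed = _parse_utm(tag)
    if parsed is None:
        raise ValueError(
            f"no geographic conversion available for CRS {crs_tag!r}")
    zone, south = parsed
    lon0 = np.radians(-183.0 + 6.0 * zone)
    phi = np.radians(lat)
    lam = np.radians(lon)

    sinp, cosp = np.sin(phi), np.cos(phi)
    tanp = sinp / cosp
    n = _A / np.sqrt(1 - _E2 * sinp**2)
    t = tanp**2
    c = _EP2 * cosp**2
    a_ = (lam - lon0) * cosp
    m = _A * ((1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256) * phi
              - (3 * _E2 / 8 + 3 * _E2**2 / 32
                 + 45 * _E2**3 / 1024) * np.sin(2 * phi)
              + (15 * _E2**2 / 256 + 45 * _E2**3 / 1024) * np.sin(4 * phi)
              - (35 * _E2**3 / 3072) * np.sin(6 * phi))

    x = _K0 * n * (a_ + (1 - t + c) * a_**3 / 6
                   + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_**5 / 120
                   ) + 500000.0
    y = _K0 * (m + n * tanp * (a_**2 / 2
                               + (5 - t + 9 * c + 4 * c**2) * a_**4 / 24
                               + (61 - 58 * t + t**2 + 600 * c
                                  - 330 * _EP2) * a_**6 / 720))
    if south:
        y = y + 10000000.0
    return x, y
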