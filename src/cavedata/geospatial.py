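"""Coordinate conversion and uncertainty for legacy degree-minute positions.

The survey records carry positions as four non-negative integers -- latitude
degrees/minutes and longitude degrees/minutes -- at whole arc-minute
precision.  All sites are Australian, so hemisphere signs are fixed rather
than inferred: latitude is southern (negative), longitude eastern (positive).
Coordinates outside a generous Australian envelope raise a warning rather
than an error, mirroring the manual site-by-site verification the rescued
data received; verified corrections enter through an override table.

The coordinate uncertainty attached to each point is the half-diagonal of
the one-resolution-cell rectangle on a sphere: a position printed to the
nearest minute can lie anywhere within half a minute in each axis, and the
east-west extent of that cell shrinks with the cosine of latitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "AUSTRALIA_ENVELOPE",
    "GeoPoint",
    "MinutesOutOfRangeError",
    "CoordinateEnvelopeWarning",
    "dms_to_decimal",
    "decompose",
    "estimate_uncertainty",
    "load_coordinate_overrides",
]

EARTH_RADIUS_M = 6_371_000.0

#: lat min/max, lon min/max of the plausibility envelope for Australian sites.
AUSTRALIA_ENVELOPE = (-45.0, -9.0, 110.0, 155.0)

DEFAULT_RESOLUTION_ARCMIN = 1.0
DEFAULT_FLOOR_M = 100.0


class MinutesOutOfRangeError(ValueError):
    code = "MINUTES_OUT_OF_RANGE"


class CoordinateEnvelopeWarning(UserWarning):
    """Converted coordinate falls outside the Australian envelope."""


@dataclass
class GeoPoint:
    decimal_latitude: float
    decimal_longitude: float
    uncertainty_m: float
    verbatim: tuple[int, int, int, int]
    amended: bool = False
    note: str = ""


def dms_to_decimal(lat_deg: int, lat_min: int, lon_deg: int, lon_min: int) -> GeoPoint:
    """Convert verbatim degree-minute integers to signed decimal degrees.

    Southern-hemisphere latitudes are negated; longitudes are east-positive.
    The verbatim integers are retained on the returned point and the default
    one-arc-minute uncertainty is attached.

    Raises :class:`MinutesOutOfRangeError` when either minutes value is
    outside [0, 60).
    """
    if not (0 <= lat_min < 60) or not (0 <= lon_min < 60):
        raise MinutesOutOfRangeError(
            f"minutes outside [0, 60): lat {lat_min}, lon {lon_min}")
    lat = -(lat_deg + lat_min / 60.0)
    lon = lon_deg + lon_min / 60.0
    lat_lo, lat_hi, lon_lo, lon_hi = AUSTRALIA_ENVELOPE
    if not (lat_lo <= lat <= lat_hi and lon_lo <= lon <= lon_hi):
        warnings.warn(
            f"coordinate ({lat:.4f}, {lon:.4f}) outside the Australian envelope",
            CoordinateEnvelopeWarning, stacklevel=2)
    point = GeoPoint(decimal_latitude=lat, decimal_longitude=lon,
                     uncertainty_m=0.0,
                     verbatim=(lat_deg, lat_min, lon_deg, lon_min))
    point.uncertainty_m = estimate_uncertainty(point)
    return point


def decompose(point: GeoPoint) -> tuple[int, int, int, int]:
    """Return the verbatim degree-minute integers of a converted point."""
    return point.verbatim


def estimate_uncertainty(
    point: Union[GeoPoint, float],
    resolution_arcmin: float = DEFAULT_RESOLUTION_ARCMIN,
    floor_m: float = DEFAULT_FLOOR_M,
) -> float:
    """Half-diagonal of the resolution cell on a spherical Earth, in metres.

    With half-resolution ``h`` (radians) and sphere radius ``k``, the
    meridional half-extent is ``h*k`` and the zonal half-extent
    ``h*k*cos(lat)``; the returned value is their hypotenuse
    ``h*k*sqrt(1 + cos^2(lat))``, clamped below by ``floor_m``.  At one
    arc-minute resolution this is ~1310 m at the equator, shrinking slowly
    toward the poles.
    """
    if resolution_arcmin <= 0:
        raise ValueError("resolution_arcmin must be positive")
    lat = point.decimal_latitude if isinstance(point, GeoPoint) else float(point)
    h = math.radians(resolution_arcmin / 60.0) / 2.0
    meridional = h * EARTH_RADIUS_M
    zonal = meridional * math.cos(math.radians(lat))
    value = math.hypot(meridional, zonal)
    return max(value, floor_m)


def load_coordinate_overrides(
    source: Union[str, Path, pd.DataFrame],
) -> dict[str, GeoPoint]:
    """Read verified coordinate corrections, keyed by location code.

    Columns: ``location_code, decimal_latitude, decimal_longitude,
    uncertainty_m, note``.  Overridden points are marked ``amended``.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    out: dict[str, GeoPoint] = {}
    for r in df.to_dict("records"):
        code = str(r["location_code"]).strip()
        lat = float(r["decimal_latitude"])
        lon = float(r["decimal_longitude"])
        unc = float(r.get("uncertainty_m") or 0) or estimate_uncertainty(lat)
        out[code] = GeoPoint(decimal_latitude=lat, decimal_longitude=lon,
                             uncertainty_m=unc, verbatim=(0, 0, 0, 0),
                             amended=True, note=str(r.get("note", "")).strip())
    return out
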