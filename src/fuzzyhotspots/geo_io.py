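"""Event ingestion, planar projection and hotspot serialization.

The clustering distance is Euclidean, so events given as WGS84 lat/lon are
projected to planar meters before clustering — by default into the UTM zone
of the data centroid.  The transverse Mercator projection is implemented
with the 6th-order Krüger series (errors well below a millimeter inside a
zone), both forward and inverse, so hotspot circles computed in the plane
can be drawn back on the globe.  Hotspots are serialized as a GeoJSON
FeatureCollection of circle-approximating polygons and as a flat CSV report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efcm_core import EventSet
from .entropy_reliability import HotspotReport


class FormatError(ValueError):
    """Input file does not have the expected columns or structure."""


class EmptyInputError(ValueError):
    """Input file contains no data rows."""


class ProjectionError(ValueError):
    """Unresolvable projection identifier."""


# ---------------------------------------------------------------------------
# event records and CSV ingestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventRecord:
    """One spatial event: identifier plus WGS84 coordinates in degrees."""

    event_id: str
    latitude: float
    longitude: float


@dataclass(frozen=True)
class ReadResult:
    """Validated event records plus a per-row report of rejected rows."""

    records: list[EventRecord]
    rejected: list[tuple[int, str]]  # (0-based data row index, reason)


_LAT_ALIASES = ("lat", "latitude")
_LON_ALIASES = ("lon", "lng", "longitude")


def _find_column(columns, aliases, kind: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(f"missing {kind} column (one of {aliases})")


def read_events(path) -> ReadResult:
    """Read an event CSV with columns event_id, lat, lon.

    Rows whose coordinates do not parse as numbers or fall outside
    [-90, 90] x [-180, 180] are rejected individually and reported; the
    remaining rows are returned as validated records.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    lat_col = _find_column(df.columns, _LAT_ALIASES, "latitude")
    lon_col = _find_column(df.columns, _LON_ALIASES, "longitude")
    id_col = _find_column(df.columns, ("event_id", "id"), "event_id")

    records: list[EventRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw = df.iloc[idx]
        try:
            lat = float(raw[lat_col])
            lon = float(raw[lon_col])
        except (TypeError, ValueError):
            rejected.append((idx, "unparseable coordinates"))
            continue
        if not (math.isfinite(lat) and math.isfinite(lon)):
            rejected.append((idx, "non-finite coordinates"))
            continue
        if not -90.0 <= lat <= 90.0:
            rejected.append((idx, f"latitude {lat} outside [-90, 90]"))
            continue
        if not -180.0 <= lon <= 180.0:
            rejected.append((idx, f"longitude {lon} outside [-180, 180]"))
            continue
        records.append(EventRecord(event_id=str(raw[id_col]),
                                   latitude=lat, longitude=lon))
    return ReadResult(records=records, rejected=rejected)


def read_planar_events(path) -> EventSet:
    """Read an already-projected event CSV with columns event_id, x, y."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    x_col = _find_column(df.columns, ("x",), "x")
    y_col = _find_column(df.columns, ("y",), "y")
    pts = df[[x_col, y_col]].to_numpy(dtype=float)
    return EventSet(points=pts, crs_tag="planar")


def write_events_csv(events: EventSet, path, labels=None) -> None:
    """Write a planar EventSet as event_id, x, y (plus optional true labels)."""
    df = pd.DataFrame({
        "event_id": [f"e{i:05d}" for i in range(events.n_points)],
        "x": events.points[:, 0],
        "y": events.points[:, 1],
    })
    if labels is not None:
        df["true_cluster"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# UTM transverse Mercator (WGS84, Krüger 6th-order series)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_E2 = _WGS84_F * (2.0 - _WGS84_F)
_E = math.sqrt(_E2)
_N = _WGS84_F / (2.0 - _WGS84_F)
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

_n = _N
# rectifying radius
_A_BAR = _WGS84_A / (1 + _n) * (1 + _n**2 / 4 + _n**4 / 64 + _n**6 / 256)
# forward (alpha) and inverse (beta) series coefficients in n
_ALPHA = (
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
    + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
)
_BETA = (
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
    - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440 + 46 * _n**5 / 105
    - 1118711 * _n**6 / 3870720,
    17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
    + 5569 * _n**6 / 90720,
    4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
    4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
    20648693 * _n**6 / 638668800,
)


def utm_zone(longitude: float, latitude: float) -> tuple[int, str]:
    """UTM zone number (1-60) and hemisphere letter for a lon/lat point."""
    zone = int(math.floor((longitude + 180.0) / 6.0)) + 1
    zone = min(max(zone, 1), 60)
    return zone, ("N" if latitude >= 0 else "S")


def _zone_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def _parse_crs_tag(crs_tag: str) -> tuple[int, str]:
    try:
        body = crs_tag.split(":", 1)[1]
        zone, hemi = int(body[:-1]), body[-1].upper()
    except (IndexError, ValueError) as exc:
        raise ProjectionError(f"cannot parse CRS tag {crs_tag!r}") from exc
    if not (1 <= zone <= 60 and hemi in "NS"):
        raise ProjectionError(f"invalid UTM zone in {crs_tag!r}")
    return zone, hemi


def transverse_mercator_forward(lat, lon, lon0: float
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Geographic -> transverse Mercator (no false origin, scaled by k0)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    sphi = np.sin(phi)
    # conformal latitude via its tangent t
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.sqrt(t * t + np.cos(lam) ** 2))
    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta += a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
    return _K0 * _A_BAR * eta, _K0 * _A_BAR * xi  # (easting, northing)


def transverse_mercator_inverse(x, y, lon0: float
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Transverse Mercator -> geographic (lat, lon in degrees)."""
    eta = np.asarray(x, dtype=float) / (_K0 * _A_BAR)
    xi = np.asarray(y, dtype=float) / (_K0 * _A_BAR)
    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p -= b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
    t_conf = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    # invert the conformal-latitude map by fixed point on tan(phi)
    asinh_t = np.arcsinh(t_conf)
    phi = np.arctan(t_conf)
    for _ in range(12):
        phi = np.arctan(np.sinh(asinh_t + _E * np.arctanh(_E * np.sin(phi))))
    return np.degrees(phi), np.degrees(lam) + lon0


def utm_forward(lat, lon, zone: int, hemisphere: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """Lat/lon (degrees) -> UTM easting/northing (meters) in a given zone."""
    e, n = transverse_mercator_forward(lat, lon, _zone_central_meridian(zone))
    e = e + _FALSE_EASTING
    if hemisphere.upper() == "S":
        n = n + _FALSE_NORTHING_SOUTH
    return e, n


def utm_inverse(easting, northing, zone: int, hemisphere: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """UTM easting/northing (meters) -> lat/lon (degrees)."""
    x = np.asarray(easting, dtype=float) - _FALSE_EASTING
    y = np.asarray(northing, dtype=float)
    if hemisphere.upper() == "S":
        y = y - _FALSE_NORTHING_SOUTH
    return transverse_mercator_inverse(x, y, _zone_central_meridian(zone))


def project_events(records: list[EventRecord], crs: str = "auto") -> EventSet:
    """Project validated lat/lon records into planar meters.

    ``crs="auto"`` picks the UTM zone of the centroid of the records;
    an explicit tag like ``"utm:33N"`` forces a zone.  The resulting
    EventSet carries the tag so circles can be inverse-projected later.
    """
    if not records:
        raise EmptyInputError("no records to project")
    lats = np.array([r.latitude for r in records])
    lons = np.array([r.longitude for r in records])
    if crs == "auto":
        zone, hemi = utm_zone(float(lons.mean()), float(lats.mean()))
    else:
        zone, hemi = _parse_crs_tag(crs)
    e, n = utm_forward(lats, lons, zone, hemi)
    return EventSet(points=np.column_stack([e, n]),
                    crs_tag=f"utm:{zone}{hemi}")


def unproject_points(points: np.ndarray, crs_tag: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Planar points back to (lat, lon) arrays; requires a UTM crs_tag."""
    zone, hemi = _parse_crs_tag(crs_tag)
    pts = np.asarray(points, dtype=float)
    return utm_inverse(pts[..., 0], pts[..., 1], zone, hemi)


def attach_centers_lonlat(reports: list[HotspotReport],
                          crs_tag: str) -> list[HotspotReport]:
    """Fill each report's lon/lat center by inverse projection (UTM tags only)."""
    if not crs_tag.startswith("utm:"):
        return list(reports)
    out = []
    for rep in reports:
        lat, lon = unproject_points(np.asarray(rep.center_xy), crs_tag)
        out.append(rep.with_lonlat(float(lon), float(lat)))
    return out


# ---------------------------------------------------------------------------
# hotspot serialization
# ---------------------------------------------------------------------------

def _circle_ring(center_xy, radius: float, n_segments: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    ring = np.column_stack([
        center_xy[0] + radius * np.cos(theta),
        center_xy[1] + radius * np.sin(theta),
    ])
    return np.vstack([ring, ring[:1]])  # closed ring


def write_hotspots_geojson(reports: list[HotspotReport], path,
                           n_segments: int = 64,
                           crs_tag: str = "planar") -> None:
    """Serialize hotspots as a GeoJSON FeatureCollection of circle polygons.

    Each circle is approximated by an ``n_segments``-vertex closed ring.
    When ``crs_tag`` names a UTM zone the vertices are inverse-projected to
    WGS84 lon/lat per the GeoJSON convention; a planar tag writes the
    projected coordinates as-is (non-standard but useful for synthetic
    studies, and flagged in the collection's properties).
    """
    if not reports:
        raise EmptyInputError("no hotspot reports to write")
    if n_segments < 8:
        raise FormatError("n_segments must be >= 8")
    geographic = crs_tag.startswith("utm:")
    features = []
    for rep in reports:
        ring = _circle_ring(rep.center_xy, rep.radius_m, n_segments)
        if geographic:
            lat, lon = unproject_points(ring, crs_tag)
            coords = np.column_stack([lon, lat])
        else:
            coords = ring
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [coords.tolist()],
            },
            "properties": {
                "id": rep.hotspot_id,
                "radius_m": rep.radius_m,
                "area_km2": rep.area_km2,
                "membership_std": rep.membership_std,
                "entropy": rep.entropy,
                "reliability": rep.reliability,
                "class": rep.reliability_class,
            },
        })
    collection = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"crs_tag": crs_tag},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh, indent=1)


def reports_to_frame(reports: list[HotspotReport]) -> pd.DataFrame:
    """Flatten hotspot reports into the standard report table."""
    rows = []
    for rep in reports:
        lat, lon = (rep.center_lonlat[1], rep.center_lonlat[0]) \
            if rep.center_lonlat else (np.nan, np.nan)
        rows.append({
            "id": rep.hotspot_id,
            "lat": lat,
            "lon": lon,
            "x": rep.center_xy[0],
            "y": rep.center_xy[1],
            "radius_m": rep.radius_m,
            "area_km2": rep.area_km2,
            "membership_std": rep.membership_std,
            "entropy": rep.entropy,
            "reliability": rep.reliability,
            "class": rep.reliability_class,
        })
    return pd.DataFrame(rows)


def write_report_csv(reports: list[HotspotReport], path) -> None:
    """Write the per-hotspot report table as CSV."""
    if not reports:
        raise EmptyInputError("no hotspot reports to write")
    reports_to_frame(reports).to_csv(path, index=False)


def read_report_csv(path) -> pd.DataFrame:
    """Read a hotspot report CSV back (for classification / analysis)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    if "reliability" not in df.columns:
        raise FormatError("report CSV must have a 'reliability' column")
    return df
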