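"""Great-circle routing and wind assistance along the migratory corridor.

The migration is modelled as the shortest (great-circle) route from the
staging site to the wintering grounds on a spherical Earth.  Wind assistance
at a grid cell is the gain in ground speed along the intended track for a
bird flying at constant airspeed that fully compensates lateral drift: the
crosswind component is cancelled by crabbing, which costs along-track
airspeed, and the along-track wind component is pocketed in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoutePoint", "Route", "great_circle", "build_route",
    "wind_assistance", "corridor_percentile",
    "ANGYORAVAK_BAY", "GRAYS_HARBOR",
]

EARTH_RADIUS_KM = 6371.0

#: default endpoints: the Angyoyaravak Bay capture site on the central
#: Yukon–Kuskokwim Delta coast and Grays Harbor, Washington, the northern
#: edge of the primary Pacific-coast wintering grounds.
ANGYORAVAK_BAY = (61.25, -165.63)
GRAYS_HARBOR = (46.93, -124.10)


@dataclass(frozen=True)
class RoutePoint:
    lat: float      # degrees, +N
    lon: float      # degrees, +E (west negative)

    def __post_init__(self):
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError("invalid coordinates")


@dataclass
class Route:
    origin: RoutePoint
    destination: RoutePoint
    distance_km: float
    initial_bearing_deg: float
    average_bearing_deg: float
    corridor_halfwidth_km: float = 250.0
    antipodal: bool = False


def _bearing(lat1, lon1, lat2, lon2) -> float:
    """Initial great-circle bearing, degrees clockwise from true north."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    x = np.sin(dl) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def _haversine_km(lat1, lon1, lat2, lon2, radius=EARTH_RADIUS_KM):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle(origin: RoutePoint, destination: RoutePoint,
                 radius: float = EARTH_RADIUS_KM):
    """Haversine distance plus initial and circular-average bearing.

    The average bearing is the circular mean of the initial and final
    bearings.  Returns ``(distance_km, initial_bearing, average_bearing,
    antipodal_flag)``; bearings are undefined (flagged) for antipodal points.
    """
    d = float(_haversine_km(origin.lat, origin.lon,
                            destination.lat, destination.lon, radius))
    antipodal = abs(d - np.pi * radius) < 1e-6 * radius
    if d < 1e-12 or antipodal:
        return d, np.nan, np.nan, antipodal
    b_init = _bearing(origin.lat, origin.lon, destination.lat, destination.lon)
    b_back = _bearing(destination.lat, destination.lon, origin.lat, origin.lon)
    b_final = (b_back + 180.0) % 360.0
    ang = np.radians([b_init, b_final])
    b_avg = float(np.degrees(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())) % 360.0)
    return d, b_init, b_avg, antipodal


def build_route(origin=ANGYORAVAK_BAY, destination=GRAYS_HARBOR,
                corridor_halfwidth_km: float = 250.0) -> Route:
    o = RoutePoint(*origin)
    dst = RoutePoint(*destination)
    d, b_init, b_avg, anti = great_circle(o, dst)
    return Route(o, dst, d, b_init, b_avg, corridor_halfwidth_km, anti)


def route_polyline(route: Route, step_km: float = 25.0) -> np.ndarray:
    """(n, 2) lat/lon samples along the great circle every ``step_km``."""
    o, d = route.origin, route.destination
    v1 = _unit(o.lat, o.lon)
    v2 = _unit(d.lat, d.lon)
    omega = np.arccos(np.clip(v1 @ v2, -1.0, 1.0))
    n = max(int(np.ceil(route.distance_km / step_km)) + 1, 2)
    f = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        pts = np.tile(v1, (n, 1))
    else:
        pts = (np.sin((1 - f)[:, None] * omega) * v1
               + np.sin(f[:, None] * omega) * v2) / np.sin(omega)
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.column_stack([lat, lon])


def _unit(lat, lon):
    p, l = np.radians(lat), np.radians(lon)
    return np.array([np.cos(p) * np.cos(l), np.cos(p) * np.sin(l), np.sin(p)])


def wind_assistance(u, v, track_deg, airspeed: float):
    """Ground-speed gain (m/s) along ``track_deg`` with full drift compensation.

    ``assistance = w_par + sqrt(Va^2 - w_perp^2) - Va`` where ``w_par`` /
    ``w_perp`` are the along- and cross-track wind components.  When the
    crosswind exceeds the airspeed the track cannot be held; those samples
    are returned as NaN (untenable) rather than raising.
    """
    if airspeed <= 0:
        raise ValueError("airspeed must be positive")
    t = np.radians(track_deg)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w_par = u * np.sin(t) + v * np.cos(t)
    w_perp = u * np.cos(t) - v * np.sin(t)
    tenable = np.abs(w_perp) < airspeed
    with np.errstate(invalid="ignore"):
        out = np.where(tenable,
                       w_par + np.sqrt(np.maximum(airspeed**2 - w_perp**2, 0.0))
                       - airspeed,
                       np.nan)
    return out if out.ndim else float(out)


def corridor_percentile(winds: pd.DataFrame, route: Route,
                        start=None, end=None, q: float = 0.80,
                        airspeed: float = 16.1) -> float:
    """q-quantile of tenable daily wind assistance within the corridor.

    Grid cells within ``route.corridor_halfwidth_km`` of the great-circle
    polyline contribute one assistance value per day (computed along the
    route's average bearing); the quantile interpolates linearly between
    order statistics.  ``start``/``end`` default to the full date span of the
    wind table.
    """
    df = winds
    if start is not None:
        df = df[pd.to_datetime(df["date"]) >= pd.Timestamp(start)]
    if end is not None:
        df = df[pd.to_datetime(df["date"]) <= pd.Timestamp(end)]
    if df.empty:
        raise ValueError("wind table does not cover the requested dates")

    cells = df[["lat", "lon"]].drop_duplicates().to_numpy()
    poly = route_polyline(route)
    dmin = np.min(
        _haversine_km(cells[:, 0][:, None], cells[:, 1][:, None],
                      poly[None, :, 0], poly[None, :, 1]), axis=1)
    in_corr = {tuple(c): ok for c, ok in zip(cells, dmin <= route.corridor_halfwidth_km)}
    mask = np.array([in_corr[(la, lo)] for la, lo in df[["lat", "lon"]].to_numpy()])
    sub = df.loc[mask]
    if sub.empty:
        raise ValueError("no grid cells inside the corridor")
    a = wind_assistance(sub["u_ms"].to_numpy(), sub["v_ms"].to_numpy(),
                        route.average_bearing_deg, airspeed)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no tenable wind samples inside the corridor")
    return float(np.quantile(a, q))
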