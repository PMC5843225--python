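"""Great-circle migratory distances along waypoint routes.

Cumulative Out-of-Africa migratory distance is the sum of great-circle legs
from an African origin through route waypoints to a population's location.
Distances use the haversine formula on a sphere of radius 6371.0088 km
(IUGG mean Earth radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popdata import GeoPoint

__all__ = ["EARTH_RADIUS_KM", "MigrationRoute", "haversine_km", "route_distance_km", "read_waypoints"]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class MigrationRoute:
    """Ordered waypoints of a migration route, origin first."""

    waypoints: tuple[GeoPoint, ...]

    def __post_init__(self) -> None:
        if len(self.waypoints) < 1:
            raise ValueError("route needs at least one waypoint")


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def route_distance_km(route: MigrationRoute, terminus: GeoPoint) -> float:
    """Cumulative distance origin -> ... -> last waypoint -> terminus, in km."""
    pts = route.waypoints + (terminus,)
    return float(sum(haversine_km(p, q) for p, q in zip(pts[:-1], pts[1:])))


def read_waypoints(path) -> MigrationRoute:
    """Read a route from TSV with header ``lat  lon``, one waypoint per line."""
    df = pd.read_csv(path, sep="\t")
    return MigrationRoute(tuple(GeoPoint(float(r["lat"]), float(r["lon"])) for _, r in df.iterrows()))
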