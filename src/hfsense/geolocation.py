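"""Mobility features from sparse smartphone location fixes.

The home location is the centroid of the most frequently occupied ~100 m grid
cell over a participant's history. Per window: the number of fixes in the
home cell (atHome), the summed Haversine distance of all fixes to home
(distToHome, km), and the counts of fixes within / beyond a 2-km radius of
home (zone1 / zone2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

#: Rounding for the "same place" grid: 3 decimal degrees ~ 111 m of latitude,
#: matching the app's ~100 m location-update granularity.
GRID_DECIMALS = 3

#: Zone-1 radius around home, km.
ZONE1_RADIUS_KM = 2.0

LOCATION_FEATURE_NAMES = ("atHome", "distToHome", "zone1", "zone2")


@dataclass
class HomeLocation:
    lat: float
    lon: float
    cell: tuple[float, float]


@dataclass
class LocationFeatures:
    atHome: float
    distToHome: float
    zone1: float
    zone2: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in LOCATION_FEATURE_NAMES}


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude must be in [-90, 90] and longitude in [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (vectorized over any argument)."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    for la, lo in ((lat1, lon1), (lat2, lon2)):
        _check_coords(la, lo)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _cells(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    return np.stack([np.round(lat, GRID_DECIMALS), np.round(lon, GRID_DECIMALS)], axis=1)


def infer_home(fixes: pd.DataFrame) -> HomeLocation:
    """Most frequently occupied grid cell; ties go to the earliest-occupied cell.

    ``fixes`` needs columns ``t``, ``lat``, ``lon`` (the participant's full
    history by default). The home coordinate is the centroid of the fixes in
    the winning cell.
    """
    if len(fixes) == 0:
        raise ValueError("cannot infer home from zero fixes")
    t = np.asarray(fixes["t"], dtype=float)
    lat = np.asarray(fixes["lat"], dtype=float)
    lon = np.asarray(fixes["lon"], dtype=float)
    _check_coords(lat, lon)
    order = np.argsort(t, kind="stable")
    t, lat, lon = t[order], lat[order], lon[order]
    cells = _cells(lat, lon)
    uniq, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if candidates.size > 1:
        # earliest first visit wins
        first_visit = np.array([t[inverse == c].min() for c in candidates])
        winner = candidates[np.argmin(first_visit)]
    else:
        winner = candidates[0]
    in_cell = inverse == winner
    return HomeLocation(
        lat=float(lat[in_cell].mean()),
        lon=float(lon[in_cell].mean()),
        cell=(float(uniq[winner, 0]), float(uniq[winner, 1])),
    )


def location_features(
    fixes: pd.DataFrame, home: HomeLocation, start_s: float, end_s: float
) -> LocationFeatures | None:
    """Window mobility features; None when the window holds no fixes."""
    if end_s <= start_s:
        raise ValueError("window must have positive length")
    t = np.asarray(fixes["t"], dtype=float)
    mask = (t >= start_s) & (t < end_s)
    if not np.any(mask):
        return None
    lat = np.asarray(fixes["lat"], dtype=float)[mask]
    lon = np.asarray(fixes["lon"], dtype=float)[mask]
    dists = np.atleast_1d(haversine_km(lat, lon, home.lat, home.lon))
    cells = _cells(lat, lon)
    at_home = int(np.sum((cells[:, 0] == home.cell[0]) & (cells[:, 1] == home.cell[1])))
    zone1 = int(np.sum(dists <= ZONE1_RADIUS_KM))
    return LocationFeatures(
        atHome=float(at_home),
        distToHome=float(dists.sum()),
        zone1=float(zone1),
        zone2=float(dists.size - zone1),
    )
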