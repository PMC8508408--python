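"""Small spherical-geometry helpers: haversine distance and an azimuthal
equidistant projection used to obtain planar metre coordinates for the
kernel-weighted methods.

All functions accept scalars or numpy arrays of longitudes/latitudes in
decimal degrees (WGS84) and use the mean Earth radius.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius, metres


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between (lon1, lat1) and (lon2, lat2).

    Broadcasts over numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def aeqd_project(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to planar x/y metres, azimuthal equidistant
    about (lon0, lat0).

    Distances from the projection centre are exactly great-circle distances;
    distances between other point pairs are mildly distorted, which is
    acceptable at the within-country scales used here.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)

    dlon = lon - lam0
    cos_c = np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlon)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k = c / sin(c), with the removable singularity at c = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_M * k * (np.cos(phi0) * np.sin(lat)
                              - np.sin(phi0) * np.cos(lat) * np.cos(dlon))
    return x, y


def local_offset_deg(lat_deg, east_m, north_m):
    """Convert a small ENU offset in metres to (dlon, dlat) degrees at lat_deg.

    First-order (equirectangular) approximation; adequate for offsets well
    below ~10 km such as point scatter and duplicate-injection distances.
    """
    lat_deg = np.asarray(lat_deg, dtype=float)
    metres_per_deg = EARTH_RADIUS_M * np.pi / 180.0
    dlat = np.asarray(north_m, dtype=float) / metres_per_deg
    dlon = np.asarray(east_m, dtype=float) / (metres_per_deg * np.cos(np.radians(lat_deg)))
    return dlon, dlat
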