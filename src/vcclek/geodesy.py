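"""Geodesic distances on the WGS84 ellipsoid.

Distances between fishing-ground centroids and ports of origin are computed
with Vincenty's inverse formula on WGS84 (a = 6378137 m, f = 1/298.257223563),
accurate to well under a millimetre for non-antipodal pairs — far below the
uncertainty of hand-drawn fishing grounds.  A point-to-polyline mode is also
provided for treating the coast as a line feature rather than a port point.
"""

from __future__ import annotations

import math
from typing import Sequence

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


def _check(lon: float, lat: float) -> None:
    if not -180.0 <= lon <= 180.0 or not -90.0 <= lat <= 90.0:
        raise ValueError(f"coordinates out of bounds: ({lon}, {lat})")


def geodesic_distance_m(lon1: float, lat1: float,
                        lon2: float, lat2: float) -> float:
    """Vincenty inverse distance in metres between two WGS84 lon/lat points.

    Falls back to a great-circle distance on the mean-radius sphere for the
    rare near-antipodal pairs where the iteration does not converge (error
    there is bounded by the flattening, ~0.5 %).
    """
    _check(lon1, lat1)
    _check(lon2, lat2)
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - WGS84_F) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - WGS84_F) * math.tan(math.radians(lat2)))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma *
                (-1.0 + 2.0 * cos_2sigma_m * cos_2sigma_m)))
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # near-antipodal: spherical fallback
        r = (2.0 * WGS84_A + WGS84_B) / 3.0
        phi1, phi2 = math.radians(lat1), math.radians(lat2)
        d = math.acos(min(1.0, max(-1.0,
            math.sin(phi1) * math.sin(phi2) +
            math.cos(phi1) * math.cos(phi2) * math.cos(L))))
        return r * d

    u2 = cos2_alpha * (WGS84_A ** 2 - WGS84_B ** 2) / WGS84_B ** 2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2) -
            B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2) *
            (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    return WGS84_B * A * (sigma - delta_sigma)


def geodesic_distance_km(lon1: float, lat1: float,
                         lon2: float, lat2: float) -> float:
    """As :func:`geodesic_distance_m`, in kilometres."""
    return geodesic_distance_m(lon1, lat1, lon2, lat2) / 1000.0


def distance_to_polyline_km(lon: float, lat: float,
                            line: Sequence[tuple[float, float]]) -> float:
    """Geodesic distance from a point to the nearest point of a polyline.

    Each segment is projected into a local equirectangular plane centred on
    the query point (exact enough at segment scale near the equator); the
    planar nearest point is then measured geodesically.  Intended for the
    coast-as-line distance mode.
    """
    _check(lon, lat)
    if len(line) < 2:
        raise ValueError("polyline needs at least two vertices")
    coslat = math.cos(math.radians(lat))

    def to_plane(p: tuple[float, float]) -> tuple[float, float]:
        return ((p[0] - lon) * coslat, p[1] - lat)

    best = math.inf
    for (p1, p2) in zip(line[:-1], line[1:]):
        x1, y1 = to_plane(p1)
        x2, y2 = to_plane(p2)
        dx, dy = x2 - x1, y2 - y1
        denom = dx * dx + dy * dy
        t = 0.0 if denom == 0.0 else max(0.0, min(1.0, -(x1 * dx + y1 * dy) / denom))
        qlon = p1[0] + t * (p2[0] - p1[0])
        qlat = p1[1] + t * (p2[1] - p1[1])
        best = min(best, geodesic_distance_km(lon, lat, qlon, qlat))
    return best
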