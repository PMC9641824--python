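"""Rhumb-line (loxodrome) geodesy on a spherical Earth.

Daily "beeline" displacements of migrating birds are measured along rhumb
lines — constant-compass-bearing paths — rather than great circles, matching
standard practice in migration track analysis.  All functions accept scalars
or numpy arrays of latitude/longitude in decimal degrees and work on a sphere
of radius ``EARTH_RADIUS_KM``.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def _wrap_lon_rad(dlon: np.ndarray) -> np.ndarray:
    """Wrap a longitude difference in radians into (-pi, pi]."""
    return -((-dlon + np.pi) % (2.0 * np.pi) - np.pi)


def _mercator_lat(phi: np.ndarray) -> np.ndarray:
    return np.log(np.tan(np.pi / 4.0 + phi / 2.0))


def rhumb_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Length in km of the loxodrome joining two points.

    Symmetric and nonnegative.  Raises ``ValueError`` when both endpoints are
    poles with differing longitude (the loxodrome is undefined there).
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    at_poles = (np.abs(lat1) >= 90.0 - 1e-12) & (np.abs(lat2) >= 90.0 - 1e-12)
    if np.any(at_poles & (np.asarray(lon1) != np.asarray(lon2))):
        raise ValueError("loxodrome undefined between poles with differing longitude")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = _wrap_lon_rad(np.radians(lon2) - np.radians(lon1))
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    # q is the cosine of latitude along the track; limit form on parallels
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(np.abs(dpsi) > 1e-12, dphi / np.where(dpsi == 0, 1, dpsi), np.cos(phi1))
    dist = np.sqrt(dphi**2 + (q * dlam) ** 2) * EARTH_RADIUS_KM
    return float(dist) if dist.ndim == 0 else dist


def rhumb_bearing(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Constant course angle in degrees clockwise from true north, in [0, 360).

    Undefined (raises ``ValueError``) for coincident scalar endpoints.
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    if lat1.ndim == 0 and float(lat1) == float(lat2) and float(lon1) == float(lon2):
        raise ValueError("bearing undefined for coincident points")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = _wrap_lon_rad(np.radians(lon2) - np.radians(lon1))
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    theta = np.degrees(np.arctan2(dlam, dpsi)) % 360.0
    return float(theta) if theta.ndim == 0 else theta


def rhumb_destination(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along a constant bearing."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    dphi = delta * np.cos(theta)
    phi2 = phi1 + dphi
    phi2 = np.clip(phi2, -np.pi / 2 + 1e-12, np.pi / 2 - 1e-12)
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(np.abs(dpsi) > 1e-12, (phi2 - phi1) / np.where(dpsi == 0, 1, dpsi), np.cos(phi1))
    dlam = delta * np.sin(theta) / q
    lam2 = _wrap_lon_rad(lam1 + dlam)
    out_lat, out_lon = np.degrees(phi2), np.degrees(lam2)
    if out_lat.ndim == 0:
        return float(out_lat), float(out_lon)
    return out_lat, out_lon


def turning_angle(azimuth_prev_deg: float, azimuth_deg: float) -> float:
    """Smallest absolute angular difference between two azimuths, in [0, 180]."""
    d = abs(azimuth_deg - azimuth_prev_deg) % 360.0
    return 360.0 - d if d > 180.0 else d


def in_northern_sector(azimuth_deg: float, west_deg: float = 270.0, east_deg: float = 90.0) -> bool:
    """Membership in the north-crossing sector (west_deg, 360) ∪ [0, east_deg).

    The migratory corridor of a northbound spring migrant: azimuths strictly
    greater than ``west_deg`` or strictly less than ``east_deg``.
    """
    if np.isnan(azimuth_deg):
        return False
    a = azimuth_deg % 360.0
    return a > west_deg or a < east_deg
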