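"""Sun--plot--drone viewing geometry and linearized covariates.

In multi-view thermography every plot is measured on many individual images,
each with its own viewing geometry.  This module computes, for one (camera,
plot, sun) triple, the raw geometric quantities (distances and angles of the
plot relative to the drone, decomposed along the sowing-row direction and the
sun-azimuth direction) and the linearized covariates used to model geometric
effects on apparent canopy temperature.

Conventions (pinned here and by the tests):

* Planar ENU frame: x = east, y = north, z = up, metres.  Azimuths are
  degrees clockwise from north.  The camera is nadir-oriented with image +y
  aligned to the camera heading.
* "Longitudinal" is the component of the plot->drone planar offset along the
  reference direction (row direction or sun-azimuth direction), positive when
  the drone is ahead of the plot in that direction.  "Lateral" is the
  perpendicular component, positive to the right of the reference direction.
* Angles are stored in degrees at interfaces, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

__all__ = [
    "SunPosition",
    "RawGeometry",
    "LINEARIZED_COVARIATE_NAMES",
    "RAW_COVARIATE_NAMES",
    "sun_position",
    "raw_geometry",
    "linearize",
    "atmospheric_attenuation",
    "apparent_temperature",
]

#: Table of linearized-covariate names, in canonical model order.  Pipeline
#: stages join on these exact strings.
LINEARIZED_COVARIATE_NAMES = (
    "Drone-Elevation-sin",
    "RowDir-lat-Dist",
    "RowDir-lat-Dist-abs",
    "RowDir-lat-Angl-cos",
    "RowDir-lat-Angl-abs",
    "RowDir-lon-Dist",
    "RowDir-lon-Dist-abs",
    "RowDir-lon-Angl-cos",
    "RowDir-lon-Angl-abs",
    "SunDir-lat-Dist",
    "SunDir-lat-Dist-abs",
    "SunDir-lat-Angl-cos",
    "SunDir-lat-Angl-abs",
    "SunDir-lon-Dist",
    "SunDir-lon-Dist-abs",
    "SunDir-lon-Angl-cos",
    "SunDir-lon-Angl-abs",
    "Interact.-SunDir-Drone",
    "Trigger-time",
    "Dist-tot",
)

#: Raw covariate column names in export order.
RAW_COVARIATE_NAMES = (
    "drone_elevation_deg",
    "dist_total_m",
    "rowdir_lat_dist_m",
    "rowdir_lon_dist_m",
    "rowdir_lat_angle_deg",
    "rowdir_lon_angle_deg",
    "sundir_lat_dist_m",
    "sundir_lon_dist_m",
    "sundir_lat_angle_deg",
    "sundir_lon_angle_deg",
)


@dataclass(frozen=True)
class SunPosition:
    """Solar position seen from the field.

    Attributes
    ----------
    azimuth : float
        Degrees clockwise from north, in [0, 360).
    elevation : float
        Degrees above the horizon, in [-90, 90].
    """

    azimuth: float
    elevation: float

    def __post_init__(self):
        if not 0.0 <= self.azimuth < 360.0:
            object.__setattr__(self, "azimuth", self.azimuth % 360.0)
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation out of range: {self.elevation}")


@dataclass(frozen=True)
class RawGeometry:
    """Raw geometric relations between one camera pose and one plot."""

    drone_elevation: float  # deg, vertical angle of the drone seen from the plot
    total_distance: float  # m
    rowdir_lat_dist: float  # m, signed
    rowdir_lon_dist: float  # m, signed
    rowdir_lat_angle: float  # deg, signed
    rowdir_lon_angle: float  # deg, signed
    sundir_lat_dist: float  # m, signed
    sundir_lon_dist: float  # m, signed
    sundir_lat_angle: float  # deg, signed
    sundir_lon_angle: float  # deg, signed
    trigger_time: float  # s from flight start
    image_xy: tuple  # plot-centre position on the focal plane (pixels from centre)


def _julian_day(dt: datetime) -> float:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    dt = dt.astimezone(timezone.utc)
    y, m = dt.year, dt.month
    d = (
        dt.day
        + dt.hour / 24.0
        + dt.minute / 1440.0
        + (dt.second + dt.microsecond / 1e6) / 86400.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def sun_position(utc_time: datetime, latitude_deg: float, longitude_deg: float) -> SunPosition:
    """NOAA-style solar position (azimuth/elevation) for a UTC timestamp.

    Accuracy is a few hundredths of a degree over the satellite era, which is
    far below the ±0.5° needed for viewing-geometry covariates.  Polar edge
    cases return well-defined values (elevation may simply stay negative).
    """
    jd = _julian_day(utc_time)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    # Geometric mean longitude / anomaly of the sun (degrees)
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    # Obliquity of the ecliptic, corrected
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )

    # Equation of time (minutes)
    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(mrad)
        + 4 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mrad)
    )

    if utc_time.tzinfo is None:
        utc_time = utc_time.replace(tzinfo=timezone.utc)
    utc = utc_time.astimezone(timezone.utc)
    minutes = utc.hour * 60.0 + utc.minute + utc.second / 60.0 + utc.microsecond / 6e7
    true_solar_min = (minutes + eot + 4.0 * longitude_deg) % 1440.0
    ha = true_solar_min / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0

    lat = math.radians(latitude_deg)
    dec = math.radians(decl)
    har = math.radians(ha)
    cos_zen = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(har)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zen = math.acos(cos_zen)
    elevation = 90.0 - math.degrees(zen)

    sin_zen = math.sin(zen)
    if abs(sin_zen) < 1e-12:
        azimuth = 180.0  # sun at zenith/nadir: azimuth degenerate but defined
    else:
        cos_az = (math.sin(dec) - math.sin(lat) * cos_zen) / (math.cos(lat) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        azimuth = math.degrees(math.acos(cos_az))
        if ha > 0:
            azimuth = 360.0 - azimuth
        azimuth = azimuth % 360.0
    return SunPosition(azimuth=azimuth, elevation=elevation)


def _azimuth_unit_vector(azimuth_deg: float) -> np.ndarray:
    """ENU planar unit vector pointing toward the given azimuth."""
    a = math.radians(azimuth_deg)
    return np.array([math.sin(a), math.cos(a)])


def _decompose(offset_xy: np.ndarray, direction: np.ndarray):
    """Longitudinal/lateral components of a planar offset wrt a unit vector.

    Longitudinal: along `direction`; lateral: perpendicular, positive to the
    right of `direction` (i.e. along the clockwise-rotated direction).
    """
    lon = float(offset_xy @ direction)
    right = np.array([direction[1], -direction[0]])  # 90° clockwise
    lat = float(offset_xy @ right)
    return lon, lat


def raw_geometry(
    camera_position,
    camera_heading: float,
    plot_center,
    row_direction,
    sun: SunPosition,
    trigger_time: float,
    focal_px: float = 800.0,
) -> RawGeometry:
    """Geometric relations between a camera pose, a plot and the sun.

    Parameters
    ----------
    camera_position : (3,) array-like
        ENU metres; must be above the plot plane.
    camera_heading : float
        Degrees clockwise from north; image +y axis points along heading.
    plot_center : array-like
        ENU metres; a 2-vector is taken to lie at z=0.
    row_direction : (2,) array-like
        Unit vector of the sowing-row direction in the ENU plane.
    sun : SunPosition
    trigger_time : float
        Seconds from flight start.
    focal_px : float
        Pinhole focal length in pixels for the focal-plane coordinates.
    """
    cam = np.asarray(camera_position, dtype=float)
    plot = np.asarray(plot_center, dtype=float)
    if plot.size == 2:
        plot = np.array([plot[0], plot[1], 0.0])
    height = cam[2] - plot[2]
    if height <= 0:
        raise ValueError("camera must be above the plot plane")

    offset = cam[:2] - plot[:2]  # plot -> drone, planar
    planar = float(np.hypot(offset[0], offset[1]))
    total = float(math.hypot(planar, height))
    elev = math.degrees(math.atan2(height, planar))

    row = np.asarray(row_direction, dtype=float)
    row = row / np.linalg.norm(row)
    row_lon, row_lat = _decompose(offset, row)
    sun_dir = _azimuth_unit_vector(sun.azimuth)
    sun_lon, sun_lat = _decompose(offset, sun_dir)

    # viewing angles: atan2(planar component, height), signed like the distance
    def ang(dist):
        return math.degrees(math.atan2(dist, height))

    # focal-plane position of the plot centre: camera frame with +y = heading,
    # +x = right of heading; nadir pinhole projection.
    head = _azimuth_unit_vector(camera_heading)
    cam_to_plot = -offset
    img_y = float(cam_to_plot @ head)
    img_x = float(cam_to_plot @ np.array([head[1], -head[0]]))
    image_xy = (focal_px * img_x / height, focal_px * img_y / height)

    return RawGeometry(
        drone_elevation=elev,
        total_distance=total,
        rowdir_lat_dist=row_lat,
        rowdir_lon_dist=row_lon,
        rowdir_lat_angle=ang(row_lat),
        rowdir_lon_angle=ang(row_lon),
        sundir_lat_dist=sun_lat,
        sundir_lon_dist=sun_lon,
        sundir_lat_angle=ang(sun_lat),
        sundir_lon_angle=ang(sun_lon),
        trigger_time=float(trigger_time),
        image_xy=image_xy,
    )


def linearize(raw: RawGeometry) -> dict:
    """Linearized covariates from raw geometry, keyed by canonical names.

    Angular covariates get cosine and absolute-value transforms, distances
    absolute-value transforms; the sun-path interaction is the longitudinal
    sun-direction distance times the sine of the drone elevation.
    """
    elev_sin = math.sin(math.radians(raw.drone_elevation))
    out = {
        "Drone-Elevation-sin": elev_sin,
        "RowDir-lat-Dist": raw.rowdir_lat_dist,
        "RowDir-lat-Dist-abs": abs(raw.rowdir_lat_dist),
        "RowDir-lat-Angl-cos": math.cos(math.radians(raw.rowdir_lat_angle)),
        "RowDir-lat-Angl-abs": abs(raw.rowdir_lat_angle),
        "RowDir-lon-Dist": raw.rowdir_lon_dist,
        "RowDir-lon-Dist-abs": abs(raw.rowdir_lon_dist),
        "RowDir-lon-Angl-cos": math.cos(math.radians(raw.rowdir_lon_angle)),
        "RowDir-lon-Angl-abs": abs(raw.rowdir_lon_angle),
        "SunDir-lat-Dist": raw.sundir_lat_dist,
        "SunDir-lat-Dist-abs": abs(raw.sundir_lat_dist),
        "SunDir-lat-Angl-cos": math.cos(math.radians(raw.sundir_lat_angle)),
        "SunDir-lat-Angl-abs": abs(raw.sundir_lat_angle),
        "SunDir-lon-Dist": raw.sundir_lon_dist,
        "SunDir-lon-Dist-abs": abs(raw.sundir_lon_dist),
        "SunDir-lon-Angl-cos": math.cos(math.radians(raw.sundir_lon_angle)),
        "SunDir-lon-Angl-abs": abs(raw.sundir_lon_angle),
        "Interact.-SunDir-Drone": raw.sundir_lon_dist * elev_sin,
        "Trigger-time": raw.trigger_time,
        "Dist-tot": raw.total_distance,
    }
    return out


def atmospheric_attenuation(path_length_m, rate_K_per_m: float = 0.001):
    """Path-length attenuation of the thermal signal, in kelvin.

    A toy linear model: the apparent temperature is reduced by
    ``rate * path_length``; at typical survey heights (~40 m) the effect is
    ~0.04 K and negligible, at 300 m it becomes visible as a point-symmetric
    pattern around nadir.
    """
    path = np.asarray(path_length_m, dtype=float)
    if np.any(path < 0):
        raise ValueError("path length must be non-negative")
    out = rate_K_per_m * path
    return float(out) if np.isscalar(path_length_m) else out


def apparent_temperature(true_temp_C, emissivity: float):
    """Apparent temperature of a grey-body target under a linear emissivity model.

    The absolute kelvin temperature is scaled by the emissivity:
    ``(T_C + 273.15) * eps``, returned in °C.  A 0.01 emissivity error at
    20 °C shifts the apparent temperature by ~2.9 K — far more than typical
    genotype-specific canopy-temperature differences, which is why relative
    (not absolute) temperatures are analysed downstream.
    """
    if not 0.0 < emissivity <= 1.0:
        raise ValueError("emissivity must be in (0, 1]")
    t = np.asarray(true_temp_C, dtype=float)
    out = (t + 273.15) * emissivity - 273.15
    return float(out) if np.isscalar(true_temp_C) else out
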