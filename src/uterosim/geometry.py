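"""Uterine geometry arithmetic.

Closed-form sizing of the term gravid uterus and its functional regions:
a 4.5 kg conceptus (fetus + placenta + amniotic fluid) at unit density
fills 4.5 L; the enclosing sphere has radius ~10.2 cm and surface area
~1300 cm^2 (an oblate spheroid of the same volume, ~1900 cm^2).  Dividing
the wall into n equal square regions gives edge lengths and, with a
tissue-level action-potential propagation speed of ~3 cm/s, the time to
recruit all tissue within one region.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

__all__ = [
    "UterineGeometry",
    "TERM_UTERUS_VOLUME_CM3",
    "OBLATE_SPHEROID_AREA_CM2",
    "AP_PROPAGATION_SPEED_CM_S",
    "BASELINE_PRESSURE_TORR",
    "PEAK_PRESSURE_TORR",
    "sphere_radius_from_volume",
    "sphere_surface_area",
    "region_edge_length",
    "recruitment_time",
    "regions_on_surface",
    "baseline_to_peak_ratio",
    "geometry_summary",
]

#: Volume of the term gravid uterine cavity, cm^3 (4.5 kg at unit density).
TERM_UTERUS_VOLUME_CM3 = 4500.0
#: Surface area of the equivalent oblate spheroid, cm^2.
OBLATE_SPHEROID_AREA_CM2 = 1900.0
#: Tissue-level action-potential propagation speed, cm/s.
AP_PROPAGATION_SPEED_CM_S = 3.0
#: Typical baseline (between-contraction) intrauterine pressure, torr.
BASELINE_PRESSURE_TORR = 15.0
#: Approximate maximal intrauterine pressure of the term uterus, torr.
PEAK_PRESSURE_TORR = 300.0


@dataclass(frozen=True)
class UterineGeometry:
    """Summary of the organ- and region-level sizing for one configuration."""

    volume_cm3: float
    sphere_radius_cm: float
    sphere_area_cm2: float
    surface_area_cm2: float
    n_regions: int
    region_edge_cm: float
    recruitment_time_s: float
    propagation_speed_cm_s: float


def sphere_radius_from_volume(volume: float) -> float:
    """Radius (cm) of a sphere holding *volume* cm^3."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (3.0 * volume / (4.0 * pi)) ** (1.0 / 3.0)


def sphere_surface_area(radius: float) -> float:
    """Surface area (cm^2) of a sphere of *radius* cm."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return 4.0 * pi * radius**2


def region_edge_length(total_area: float, n_regions: int) -> float:
    """Edge (cm) of each of *n_regions* equal square tiles of *total_area*."""
    if total_area <= 0 or n_regions <= 0:
        raise ValueError("total area and region count must be positive")
    return (total_area / n_regions) ** 0.5


def recruitment_time(
    edge_length: float, speed: float = AP_PROPAGATION_SPEED_CM_S
) -> float:
    """Seconds for one action potential to sweep a region edge."""
    if edge_length <= 0 or speed <= 0:
        raise ValueError("edge length and speed must be positive")
    return edge_length / speed


def regions_on_surface(total_area: float, region_area: float) -> float:
    """How many regions of *region_area* tile *total_area* (unrounded)."""
    if total_area <= 0 or region_area <= 0:
        raise ValueError("areas must be positive")
    return total_area / region_area


def baseline_to_peak_ratio(
    baseline: float = BASELINE_PRESSURE_TORR, peak: float = PEAK_PRESSURE_TORR
) -> float:
    """Baseline over peak intrauterine pressure (~1/20 in labor).

    On the simulation's 0-10 activity scale this is why the minimum
    pressure should sit near 0.5 when peaks reach ~10.
    """
    if baseline < 0 or peak <= 0:
        raise ValueError("pressures must be positive")
    return baseline / peak


def geometry_summary(
    volume: float = TERM_UTERUS_VOLUME_CM3,
    surface_area: float = OBLATE_SPHEROID_AREA_CM2,
    n_regions: int = 25,
    speed: float = AP_PROPAGATION_SPEED_CM_S,
) -> UterineGeometry:
    """Assemble the full sizing table for a given region count."""
    radius = sphere_radius_from_volume(volume)
    edge = region_edge_length(surface_area, n_regions)
    return UterineGeometry(
        volume_cm3=volume,
        sphere_radius_cm=radius,
        sphere_area_cm2=sphere_surface_area(radius),
        surface_area_cm2=surface_area,
        n_regions=n_regions,
        region_edge_cm=edge,
        recruitment_time_s=recruitment_time(edge, speed),
        propagation_speed_cm_s=speed,
    )
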