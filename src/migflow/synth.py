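"""Synthetic radar cases with known ground truth.

Generates site layouts, time-varying layered flows and density surfaces, and
writes them in the exact case-study file dialects, so the whole pipeline
(screening, aggregation, field reconstruction, both visualizations) is
testable without downloading any real case. The flow kinds emulate phenomena
seen in nocturnal migration: a broad-front uniform flow along a bearing,
altitude layering with per-band directions and higher densities aloft, and a
slow clockwise drift of the migration axis over the night. Ground truth is
available noise-free through :func:`truth_at` for recovery tests.

Default study conditions mirror the two case-study networks: a 5-station
~300x300 km EU-like layout with 200-m bins to 4000 m, and a 13-station
~1000x800 km US-like layout with 100-m bins to 3000 m; 5-minute scan
timestamps; densities of order 10^2 birds km^-3 on a migration night and
ground speeds around 10 m s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import box

from .field import AzimuthalEquidistant
from .io import Basemap, CaseStudy, save_case
from .preprocess import PreprocessConfig, preprocess
from .records import ProfileRecord, RadarSite

#: 5 stations spread over roughly 300 x 300 km (Low Countries-like geometry)
EU5_SITES = (
    RadarSite("eu01", "north-coastal", 4.79, 52.95),
    RadarSite("eu02", "central", 5.18, 52.10),
    RadarSite("eu03", "west-coastal", 3.07, 51.19),
    RadarSite("eu04", "inland", 4.46, 50.90),
    RadarSite("eu05", "southeast", 5.51, 49.91),
)

#: 13 stations over roughly 1000 x 800 km (northeastern-US-like geometry)
US13_SITES = (
    RadarSite("us01", "s01", -77.5, 38.9),
    RadarSite("us02", "s02", -76.1, 39.7),
    RadarSite("us03", "s03", -74.4, 39.9),
    RadarSite("us04", "s04", -73.9, 40.9),
    RadarSite("us05", "s05", -72.6, 41.5),
    RadarSite("us06", "s06", -71.1, 41.7),
    RadarSite("us07", "s07", -70.0, 41.9),
    RadarSite("us08", "s08", -71.6, 42.9),
    RadarSite("us09", "s09", -73.8, 42.6),
    RadarSite("us10", "s10", -75.7, 43.0),
    RadarSite("us11", "s11", -77.7, 42.2),
    RadarSite("us12", "s12", -70.9, 43.9),
    RadarSite("us13", "s13", -73.2, 44.5),
)


@dataclass(frozen=True)
class FlowSpec:
    """Ground-truth flow + density model for a synthetic case.

    kinds
        ``uniform``    constant velocity along ``bearing_deg`` at ``speed``;
        ``rotation``   solid-body rotation about the layout centroid with
                       period ``rotation_period_h`` (counter-clockwise);
        ``shear``      u = shear_rate * y, v = 0 (linear horizontal shear);
        ``layered``    per-altitude-band bearings from ``band_bearings``;
        ``time_shift`` bearing drifts clockwise ``drift_deg_per_hour``.

    The density surface is ``base_density`` birds km^-3, scaled per band by
    ``band_density_factors`` (layering), stepped by ``north_south_ratio``
    for y > 0 (northern half), and per station by ``density_by_site``.
    Noise is zero-mean Gaussian jitter: ``noise_v`` m s^-1 on each velocity
    component and ``noise_density`` (relative) on density, clipped at zero.
    """

    kind: str = "uniform"
    speed: float = 10.0  # m/s
    bearing_deg: float = 41.0  # degrees clockwise from north
    rotation_period_h: float = 12.0
    shear_rate: float = 0.05  # (m/s) per km of y
    band_bearings: Optional[tuple[float, ...]] = None
    drift_deg_per_hour: float = 10.0
    base_density: float = 150.0  # birds km^-3
    band_density_factors: Optional[tuple[float, ...]] = None
    north_south_ratio: float = 1.0
    density_by_site: Optional[dict] = None
    noise_v: float = 0.0
    noise_density: float = 0.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.base_density < 0:
            raise ValueError("base_density must be >= 0")
        if self.kind not in ("uniform", "rotation", "shear", "layered", "time_shift"):
            raise ValueError(f"unknown flow kind {self.kind!r}")


def bearing_to_uv(bearing_deg: float, speed: float) -> tuple[float, float]:
    """Bearing (deg clockwise from north) + speed -> (u east, v north)."""
    b = math.radians(bearing_deg)
    return speed * math.sin(b), speed * math.cos(b)


def truth_at(
    flow: FlowSpec,
    xy: np.ndarray,
    t: datetime,
    band_index: int = 0,
    t0: Optional[datetime] = None,
) -> tuple[float, float, float]:
    """Noise-free (u, v, rho) of the ground-truth flow at a projected point.

    ``xy`` is in km relative to the layout centroid (the projection origin);
    ``t0`` anchors the time-dependent kinds (defaults to ``t``).
    """
    x, y = float(xy[0]), float(xy[1])
    if flow.kind == "uniform":
        u, v = bearing_to_uv(flow.bearing_deg, flow.speed)
    elif flow.kind == "rotation":
        omega = 2.0 * math.pi / (flow.rotation_period_h * 3600.0)  # rad/s
        # solid body: speed (m/s) = omega * r(km) * 1000
        u, v = -omega * y * 1000.0, omega * x * 1000.0
    elif flow.kind == "shear":
        u, v = flow.shear_rate * y, 0.0
    elif flow.kind == "layered":
        bearings = flow.band_bearings or (flow.bearing_deg,)
        u, v = bearing_to_uv(bearings[band_index % len(bearings)], flow.speed)
    else:  # time_shift
        hours = 0.0 if t0 is None else (t - t0).total_seconds() / 3600.0
        u, v = bearing_to_uv(flow.bearing_deg + flow.drift_deg_per_hour * hours, flow.speed)
    rho = flow.base_density
    if flow.band_density_factors:
        rho *= flow.band_density_factors[band_index % len(flow.band_density_factors)]
    if y > 0:
        rho *= flow.north_south_ratio
    return u, v, max(rho, 0.0)


def layout_sites(layout: Union[str, Sequence[RadarSite]]) -> list[RadarSite]:
    if isinstance(layout, str):
        key = layout.lower()
        if key == "eu5":
            return list(EU5_SITES)
        if key == "us13":
            return list(US13_SITES)
        raise ValueError(f"unknown layout {layout!r} (expected 'eu5' or 'us13')")
    return list(layout)


def default_config(layout: Union[str, Sequence[RadarSite]]) -> PreprocessConfig:
    if isinstance(layout, str) and layout.lower() == "us13":
        return PreprocessConfig.us_default()
    return PreprocessConfig.eu_default()


def generate_case(
    layout: Union[str, Sequence[RadarSite]] = "eu5",
    flow: FlowSpec = FlowSpec(),
    start: datetime = datetime(2013, 4, 5, 18, 0, tzinfo=timezone.utc),
    hours: float = 4.0,
    seed: int = 0,
    config: Optional[PreprocessConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> CaseStudy:
    """Build (and optionally write) a complete synthetic case study.

    Raw profile records sample the ground-truth flow at each site, 5-minute
    timestamp and native altitude bin, plus the configured noise; they are
    run through the standard screening/aggregation to produce the
    aggregated table. The basemap is a rectangle around the network.
    Deterministic for a given seed (identical files byte for byte).
    """
    sites = layout_sites(layout)
    config = config or default_config(layout)
    rng = np.random.default_rng(seed)
    projection = AzimuthalEquidistant.for_sites(sites)
    site_xy = {s.radar_id: projection.project_site(s) for s in sites}

    n_times = int(round(hours * 12))  # 5-minute cadence
    times = [start + timedelta(minutes=5 * i) for i in range(n_times)]
    bin_floors = np.arange(0.0, config.altitude_ceiling, config.bin_width)

    raw: list[ProfileRecord] = []
    for t in times:
        for site in sites:
            xy = site_xy[site.radar_id]
            site_factor = (flow.density_by_site or {}).get(site.radar_id, 1.0)
            for floor in bin_floors:
                band = config.band_of(floor)
                bi = config.bands.index(band) if band is not None else 0
                u, v, rho = truth_at(flow, xy, t, band_index=bi, t0=start)
                rho *= site_factor
                if flow.noise_v > 0:
                    u += rng.normal(0.0, flow.noise_v)
                    v += rng.normal(0.0, flow.noise_v)
                if flow.noise_density > 0:
                    rho *= 1.0 + rng.normal(0.0, flow.noise_density)
                raw.append(
                    ProfileRecord(
                        radar_id=site.radar_id,
                        timestamp=t,
                        bin_floor=float(floor),
                        bin_width=float(config.bin_width),
                        density=max(float(rho), 0.0),
                        u=float(u),
                        v=float(v),
                    )
                )

    aggregated = preprocess(raw, config)

    lons = [s.longitude for s in sites]
    lats = [s.latitude for s in sites]
    basemap = Basemap([box(min(lons) - 1.0, min(lats) - 1.0, max(lons) + 1.0, max(lats) + 1.0)])

    case = CaseStudy(
        sites=sites,
        records=aggregated,
        basemap=basemap,
        config=config,
        raw_records=raw,
    )
    if out_dir is not None:
        save_case(case, out_dir)
    return case
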