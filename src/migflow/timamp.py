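"""Time Integrated Multi-Altitude Migration Patterns (TIMAMP).

A static pathline visualization: each pathline is the expected trajectory of
a virtual group of migrants over a 1-8 h window, integrated through the
time-varying velocity field with the two-stage Runge-Kutta (Heun) method at
20-minute increments. Pathlines are anchored probabilistically so that their
spatial distribution tracks the observed bird density:

1. the area is covered by a lattice of cells (10x10 km EU-style, 20x20 km
   US-style) whose centres lie within 75 km of a radar;
2. crossing the lattice with the altitude strata gives volumes, and the
   window-averaged interpolated density times the volume gives the expected
   number of migrants in each volume;
3. dividing by the migrants-per-path count gives the expected number of
   pathlines anchored in that volume, apportioned uniformly over the
   window's 20-minute steps and realized as floor + Bernoulli(remainder);
4. each anchor integrates half the window backward and half forward from
   the midpoint of its time step, giving a centrally anchored pathline.

The drawn curves are cardinal-spline smoothed, their thickness follows the
interpolated density along the path, and a dot marks the temporal endpoint
(the direction birds are heading).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .field import (
    AzimuthalEquidistant,
    FieldUndefinedError,
    TimeRangeError,
    VectorField,
)
from .io import CaseStudy
from .preprocess import PreprocessConfig, preprocess
from .records import AltitudeBand, RadarSite, ValidationError, ensure_utc

#: migrants-per-path menu offered by the interactive controls
MIGRANTS_PER_PATH_MENU = (10_000, 25_000, 50_000, 100_000, 250_000, 500_000)
MAX_DURATION_HOURS = 8
MAX_STRATA = 6


def strata_bands(strata_count: int, altitude_ceiling: float) -> tuple[AltitudeBand, ...]:
    """Partition [0, ceiling] into ``strata_count`` equal altitude bands."""
    edges = np.linspace(0.0, altitude_ceiling, strata_count + 1)
    return tuple(AltitudeBand(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class TimampConfig:
    """Controls of one TIMAMP rendering.

    ``duration_hours`` must be an integer in [1, 8]; ``strata_count`` one of
    1-6; ``migrants_per_path`` any positive count (the interactive menu
    offers 10/25/50/100/250/500 thousand).
    """

    window_start: datetime
    duration_hours: int = 6
    strata_count: int = 5
    migrants_per_path: int = 50_000
    cell_km: float = 10.0
    radius_km: float = 75.0
    step_minutes: int = 20
    spline_tension: float = 0.5
    thickness_min: float = 0.5
    thickness_max: float = 6.0
    density_scale: float = 500.0  # birds km^-3 mapped to thickness_max
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_start", ensure_utc(self.window_start))
        if not (1 <= int(self.duration_hours) <= MAX_DURATION_HOURS):
            raise ValidationError(
                f"duration_hours must be in [1, {MAX_DURATION_HOURS}], got {self.duration_hours}"
            )
        if not (1 <= int(self.strata_count) <= MAX_STRATA):
            raise ValidationError(f"strata_count must be in [1, {MAX_STRATA}]")
        if self.migrants_per_path <= 0:
            raise ValidationError("migrants_per_path must be > 0")
        if self.cell_km <= 0 or self.radius_km <= 0 or self.step_minutes <= 0:
            raise ValidationError("cell_km, radius_km and step_minutes must be > 0")
        if not 0.0 <= self.spline_tension <= 1.0:
            raise ValidationError("spline_tension must be in [0, 1]")
        if self.duration_hours * 60 < self.step_minutes:
            raise ValidationError("window shorter than one integration step")

    @property
    def n_steps(self) -> int:
        return (self.duration_hours * 60) // self.step_minutes

    @property
    def step(self) -> timedelta:
        return timedelta(minutes=self.step_minutes)

    @property
    def window_end(self) -> datetime:
        return self.window_start + timedelta(hours=self.duration_hours)


@dataclass
class GridVolume:
    """One lattice cell crossed with one altitude stratum."""

    i: int
    j: int
    band: AltitudeBand
    band_index: int
    origin_xy: np.ndarray  # lower-left corner, projected km
    cell_km: float
    thickness_km: float
    mean_density: Optional[float] = None  # birds km^-3, window mean
    expected_migrants: float = 0.0

    @property
    def center(self) -> np.ndarray:
        return self.origin_xy + self.cell_km / 2.0

    @property
    def volume_km3(self) -> float:
        return self.cell_km**2 * self.thickness_km


@dataclass
class Anchor:
    point: np.ndarray  # projected km
    band_index: int
    band: AltitudeBand
    time_step: int  # index of the window's step this anchor belongs to


@dataclass
class Pathline:
    """A centrally anchored trajectory with per-vertex density."""

    anchor: Anchor
    anchor_time: datetime
    vertices: np.ndarray  # (m, 2) time-ordered projected km
    times: list  # datetime per vertex
    densities: np.ndarray  # (m,) birds km^-3, NaN where undefined
    anchor_index: int  # position of the anchor within vertices
    truncated_backward: bool = False
    truncated_forward: bool = False


@dataclass
class StyledPathline:
    """Spline-smoothed, thickness-mapped curve ready for drawing."""

    pathline: Pathline
    curve: np.ndarray  # (M, 2) dense polyline
    thickness: np.ndarray  # (M,) linewidths
    endpoint: np.ndarray  # (2,) temporally last vertex (the travel direction)


# ---------------------------------------------------------------------------
# lattice and anchoring
# ---------------------------------------------------------------------------

def build_lattice(
    sites: Sequence[RadarSite],
    config: TimampConfig,
    bands: Sequence[AltitudeBand],
    projection: Optional[AzimuthalEquidistant] = None,
    altitude_ceiling: float = 4000.0,
) -> list[GridVolume]:
    """Axis-aligned cells (edge ``cell_km``) whose centres lie within
    ``radius_km`` of the nearest radar, crossed with the altitude bands."""
    if not sites:
        raise ValidationError("at least one radar site is required")
    projection = projection or AzimuthalEquidistant.for_sites(sites)
    site_xy = np.array([projection.project_site(s) for s in sites])
    cell = config.cell_km
    r = config.radius_km
    # snap the lattice to multiples of the cell edge so it is layout-stable
    i0 = math.floor((site_xy[:, 0].min() - r) / cell)
    i1 = math.ceil((site_xy[:, 0].max() + r) / cell)
    j0 = math.floor((site_xy[:, 1].min() - r) / cell)
    j1 = math.ceil((site_xy[:, 1].max() + r) / cell)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    centers = np.stack([(ii + 0.5) * cell, (jj + 0.5) * cell], axis=1)
    d2 = ((centers[:, None, :] - site_xy[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    keep = d2 <= r**2
    volumes = []
    for bi, band in enumerate(bands):
        thick = band.depth_m(altitude_ceiling) / 1000.0
        for i, j in zip(ii[keep], jj[keep]):
            volumes.append(
                GridVolume(
                    i=int(i),
                    j=int(j),
                    band=band,
                    band_index=bi,
                    origin_xy=np.array([i * cell, j * cell], dtype=float),
                    cell_km=cell,
                    thickness_km=thick,
                )
            )
    return volumes


def window_steps(field: VectorField, config: TimampConfig) -> list[datetime]:
    """Starts of the window's integration steps that the field covers."""
    return [
        config.window_start + s * config.step
        for s in range(config.n_steps)
        if field.t0 <= config.window_start + s * config.step < field.t_end
    ]


def volume_migrants(
    volume: GridVolume, field: VectorField, config: TimampConfig
) -> float:
    """Expected migrants in a volume: window-mean density x volume.

    The density is IDW-interpolated at the cell centre in each of the
    window's 20-minute intervals and averaged; intervals where the density
    field is undefined are skipped, and a volume with no defined interval
    has zero expected migrants.
    """
    values = []
    for t in window_steps(field, config):
        try:
            values.append(field.density(volume.center, t, volume.band_index))
        except (FieldUndefinedError, TimeRangeError):
            continue
    if not values:
        volume.mean_density = None
        volume.expected_migrants = 0.0
        return 0.0
    mean_density = float(np.mean(values))
    volume.mean_density = mean_density
    volume.expected_migrants = mean_density * volume.volume_km3
    return volume.expected_migrants


def compute_migrants(
    volumes: Sequence[GridVolume], field: VectorField, config: TimampConfig
) -> float:
    """Fill ``expected_migrants`` on every volume; returns the total."""
    return float(sum(volume_migrants(v, field, config) for v in volumes))


def draw_anchors(
    volumes: Sequence[GridVolume],
    config: TimampConfig,
    rng: np.random.Generator,
    n_steps: Optional[int] = None,
) -> list[Anchor]:
    """Sample pathline anchors with density-proportional probability.

    Per volume the expected pathline count is expected_migrants /
    migrants_per_path, split uniformly over the window's steps; each
    (volume, step) realizes floor(lambda) anchors plus a Bernoulli extra on
    the fractional part, placed uniformly within the cell footprint. The
    expected total is therefore sum(expected_migrants) / migrants_per_path.
    """
    if config.migrants_per_path <= 0:
        raise ValidationError("migrants_per_path must be > 0")
    n_steps = n_steps or config.n_steps
    anchors: list[Anchor] = []
    for vol in volumes:
        lam_step = vol.expected_migrants / config.migrants_per_path / n_steps
        if lam_step <= 0:
            continue
        base = int(math.floor(lam_step))
        frac = lam_step - base
        for step_idx in range(n_steps):
            count = base + (1 if rng.random() < frac else 0)
            for _ in range(count):
                offset = rng.uniform(0.0, vol.cell_km, size=2)
                anchors.append(
                    Anchor(
                        point=vol.origin_xy + offset,
                        band_index=vol.band_index,
                        band=vol.band,
                        time_step=step_idx,
                    )
                )
    return anchors


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def heun_step(
    point: np.ndarray,
    t: datetime,
    h_seconds: float,
    field: VectorField,
    band: int,
) -> np.ndarray:
    """One two-stage Runge-Kutta (Heun) step of signed length ``h_seconds``.

    k1 = V(t, x); k2 = V(t + h, x + h k1); x' = x + (h/2)(k1 + k2), with
    velocities converted from m/s to km/s. Exact for fields constant in
    space and time; second-order accurate otherwise. Raises
    FieldUndefinedError/TimeRangeError if either stage is unevaluable (the
    caller truncates the pathline there).
    """
    t2 = t + timedelta(seconds=h_seconds)
    k1 = np.asarray(field.velocity(point, t, band), float) / 1000.0
    k2 = np.asarray(field.velocity(point + h_seconds * k1, t2, band), float) / 1000.0
    return point + (h_seconds / 2.0) * (k1 + k2)


def _vertex_density(field: VectorField, point, t, band) -> float:
    try:
        return field.density(point, t, band)
    except (FieldUndefinedError, TimeRangeError):
        return float("nan")


def integrate_pathline(
    anchor: Anchor, field: VectorField, config: TimampConfig
) -> Pathline:
    """Integrate backward then forward from the anchor's central time.

    With n = duration/step total steps the pathline takes ceil(n/2)
    backward and floor(n/2) forward Heun steps of +-step_minutes from the
    midpoint of the anchor's time step. Where the field runs out (time
    range or no vector samples) the pathline is truncated and flagged.
    """
    h = config.step_minutes * 60.0
    n = config.n_steps
    n_back = (n + 1) // 2
    n_fwd = n // 2
    t_anchor = config.window_start + (anchor.time_step + 0.5) * config.step
    point = np.asarray(anchor.point, float)

    back: list[tuple[np.ndarray, datetime]] = []
    p, t = point, t_anchor
    truncated_b = False
    for _ in range(n_back):
        try:
            p = heun_step(p, t, -h, field, anchor.band_index)
        except (FieldUndefinedError, TimeRangeError):
            truncated_b = True
            break
        t = t - config.step
        back.append((p.copy(), t))

    fwd: list[tuple[np.ndarray, datetime]] = []
    p, t = point, t_anchor
    truncated_f = False
    for _ in range(n_fwd):
        try:
            p = heun_step(p, t, +h, field, anchor.band_index)
        except (FieldUndefinedError, TimeRangeError):
            truncated_f = True
            break
        t = t + config.step
        fwd.append((p.copy(), t))

    seq = back[::-1] + [(point, t_anchor)] + fwd
    vertices = np.array([pt for pt, _ in seq])
    times = [tt for _, tt in seq]
    densities = np.array(
        [_vertex_density(field, pt, tt, anchor.band_index) for pt, tt in seq]
    )
    return Pathline(
        anchor=anchor,
        anchor_time=t_anchor,
        vertices=vertices,
        times=times,
        densities=densities,
        anchor_index=len(back),
        truncated_backward=truncated_b,
        truncated_forward=truncated_f,
    )


# ---------------------------------------------------------------------------
# smoothing and styling
# ---------------------------------------------------------------------------

def cardinal_spline(
    points: np.ndarray, tension: float = 0.5, samples_per_segment: int = 12
) -> np.ndarray:
    """Interpolating cardinal spline through ``points``.

    Tangents are tension * (p[i+1] - p[i-1]) / 2 (one-sided at the ends),
    so tension = 1 is the Catmull-Rom spline and tension = 0 degenerates to
    the input polyline. The curve passes through every control point.
    """
    pts = np.asarray(points, dtype=float)
    m = len(pts)
    if m < 2:
        return pts.copy()
    tangents = np.zeros_like(pts)
    tangents[0] = tension * (pts[1] - pts[0])
    tangents[-1] = tension * (pts[-1] - pts[-2])
    if m > 2:
        tangents[1:-1] = tension * (pts[2:] - pts[:-2]) / 2.0
    ts = np.linspace(0.0, 1.0, samples_per_segment + 1)
    h00 = 2 * ts**3 - 3 * ts**2 + 1
    h10 = ts**3 - 2 * ts**2 + ts
    h01 = -2 * ts**3 + 3 * ts**2
    h11 = ts**3 - ts**2
    out = []
    for i in range(m - 1):
        seg = (
            np.outer(h00, pts[i])
            + np.outer(h10, tangents[i])
            + np.outer(h01, pts[i + 1])
            + np.outer(h11, tangents[i + 1])
        )
        out.append(seg[:-1] if i < m - 2 else seg)
    return np.vstack(out)


def smooth_and_style(
    pathline: Pathline, config: TimampConfig, samples_per_segment: int = 12
) -> StyledPathline:
    """Cardinal-spline smooth a pathline and map density to line thickness.

    thickness = t_min + (t_max - t_min) * density / density_scale, clipped
    to [t_min, t_max]; undefined densities draw at t_min. A single-point
    pathline (zero flow) yields only the endpoint dot.
    """
    verts = pathline.vertices
    distinct = np.any(np.ptp(verts, axis=0) > 1e-12)
    if len(verts) < 2 or not distinct:
        pt = verts[-1] if len(verts) else pathline.anchor.point
        return StyledPathline(
            pathline=pathline,
            curve=pt.reshape(1, 2),
            thickness=np.array([config.thickness_min]),
            endpoint=np.asarray(pt, float),
        )
    curve = cardinal_spline(verts, config.spline_tension, samples_per_segment)
    dens = np.nan_to_num(pathline.densities, nan=0.0)
    span = config.thickness_max - config.thickness_min
    vert_thick = np.clip(
        config.thickness_min + span * dens / config.density_scale,
        config.thickness_min,
        config.thickness_max,
    )
    # interpolate per-vertex thickness along the dense curve parameter
    u_vert = np.arange(len(verts), dtype=float)
    u_curve = np.linspace(0.0, len(verts) - 1.0, len(curve))
    thickness = np.interp(u_curve, u_vert, vert_thick)
    return StyledPathline(
        pathline=pathline,
        curve=curve,
        thickness=thickness,
        endpoint=np.asarray(verts[-1], float),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class TimampResult:
    config: TimampConfig
    bands: tuple[AltitudeBand, ...]
    field: VectorField
    volumes: list
    anchors: list
    pathlines: list  # StyledPathline
    total_expected_migrants: float


def timamp_field(case: CaseStudy, config: TimampConfig) -> tuple[VectorField, tuple[AltitudeBand, ...]]:
    """Velocity/density field over the TIMAMP strata for a case.

    Prefers re-aggregating the case's raw profiles into the requested
    strata; falls back to the shipped aggregates when their bands already
    match (otherwise the strata selection is unsatisfiable).
    """
    bands = strata_bands(config.strata_count, case.config.altitude_ceiling)
    if case.raw_records is not None:
        pcfg = PreprocessConfig(
            cross_section=case.config.cross_section,
            density_threshold=case.config.density_threshold,
            bin_floor_min=case.config.bin_floor_min,
            altitude_ceiling=case.config.altitude_ceiling,
            interval_minutes=case.config.interval_minutes,
            scan_rounding_minutes=case.config.scan_rounding_minutes,
            bands=bands,
            bin_width=case.config.bin_width,
        )
        records = preprocess(case.raw_records, pcfg)
    else:
        record_bands = {r.band for r in case.records}
        if record_bands != set(bands):
            raise ValidationError(
                f"case provides no raw profiles and its aggregated bands "
                f"{sorted(b.label for b in record_bands)} do not match the "
                f"requested {config.strata_count} strata"
            )
        records = case.records
    field = VectorField.from_aggregates(case.sites, records, config=case.config)
    return field, bands


def run_timamp(case: CaseStudy, config: TimampConfig) -> TimampResult:
    """Compute a full TIMAMP pathline set for a case study."""
    field, bands = timamp_field(case, config)
    volumes = build_lattice(
        case.sites,
        config,
        bands,
        projection=field.projection,
        altitude_ceiling=case.config.altitude_ceiling,
    )
    total = compute_migrants(volumes, field, config)
    rng = np.random.default_rng(config.seed)
    anchors = draw_anchors(volumes, config, rng)
    pathlines = [
        smooth_and_style(integrate_pathline(a, field, config), config) for a in anchors
    ]
    return TimampResult(
        config=config,
        bands=bands,
        field=field,
        volumes=volumes,
        anchors=anchors,
        pathlines=pathlines,
        total_expected_migrants=total,
    )


def pathlines_to_geojson(
    result: TimampResult, path: Optional[Union[str, Path]] = None
) -> dict:
    """Export pathlines as a GeoJSON FeatureCollection (lon/lat LineStrings)."""
    proj = result.field.projection
    feats = []
    for sp in result.pathlines:
        lon, lat = proj.inverse(sp.curve[:, 0], sp.curve[:, 1])
        coords = np.stack([np.atleast_1d(lon), np.atleast_1d(lat)], axis=1)
        gtype = "Point" if len(coords) == 1 else "LineString"
        geometry = {
            "type": gtype,
            "coordinates": coords[0].tolist() if gtype == "Point" else coords.tolist(),
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "band": sp.pathline.anchor.band.label,
                    "band_index": sp.pathline.anchor.band_index,
                    "anchor_time": sp.pathline.anchor_time.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "thickness": [round(float(t), 3) for t in sp.thickness],
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        Path(path).write_text(json.dumps(doc) + "\n")
    return doc
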