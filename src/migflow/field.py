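"""Continuous velocity/density fields from sparse per-radar aggregates.

Radars sample the migration velocity field at a handful of irregular
locations. A complete planar field is reconstructed by inverse squared
distance weighting (IDW) over the ``k`` nearest vector-bearing radars
(``k = 5``, the number used for the case studies), independently per
20-minute interval and altitude band. Bird density is interpolated the same
way as a scalar field.

Interpolation happens in a local azimuthal-equidistant projection (km)
centred on the radar-network centroid, so results are independent of any
rendering resolution; conversion to pixels is left to the render module.

Zero-velocity-convention samples (u = v = 0, "measured, no migration") take
part in the interpolation and pull the field toward rest; missing samples
are excluded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .preprocess import PreprocessConfig
from .records import AggregatedRecord, AltitudeBand, RadarSite, ensure_utc

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius


class FieldUndefinedError(ValueError):
    """No vector/density-bearing sample is available; callers render no flow."""


class TimeRangeError(ValueError):
    """Query instant outside the field's covered time range."""


class AzimuthalEquidistant:
    """Spherical azimuthal equidistant projection, km units.

    Distances and azimuths from the projection origin are preserved
    exactly, which suits a radar network a few hundred km across.
    """

    def __init__(self, lon0: float, lat0: float, radius_km: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius_km = radius_km
        self._sin0 = math.sin(math.radians(lat0))
        self._cos0 = math.cos(math.radians(lat0))

    @classmethod
    def for_sites(cls, sites: Sequence[RadarSite]) -> "AzimuthalEquidistant":
        """Projection centred on the (lon, lat) centroid of the sites."""
        lon0 = sum(s.longitude for s in sites) / len(sites)
        lat0 = sum(s.latitude for s in sites) / len(sites)
        return cls(lon0, lat0)

    def forward(self, lon, lat):
        """lon/lat degrees -> (x, y) km east/north of the origin."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        sinp, cosp = np.sin(phi), np.cos(phi)
        cosc = np.clip(self._sin0 * sinp + self._cos0 * cosp * np.cos(lam), -1.0, 1.0)
        c = np.arccos(cosc)
        sinc = np.sin(c)
        with np.errstate(invalid="ignore"):
            k = np.where(sinc > 1e-15, c / np.where(sinc > 1e-15, sinc, 1.0), 1.0)
        x = self.radius_km * k * cosp * np.sin(lam)
        y = self.radius_km * k * (self._cos0 * sinp - self._sin0 * cosp * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / self.radius_km
        sinc, cosc = np.sin(c), np.cos(c)
        safe = rho > 1e-12
        rho_s = np.where(safe, rho, 1.0)
        phi = np.where(
            safe,
            np.arcsin(np.clip(cosc * self._sin0 + y * sinc * self._cos0 / rho_s, -1, 1)),
            math.radians(self.lat0),
        )
        lam = np.where(
            safe,
            np.arctan2(x * sinc, rho_s * cosc * self._cos0 - y * sinc * self._sin0),
            0.0,
        )
        return self.lon0 + np.degrees(lam), np.degrees(phi)

    def project_site(self, site: RadarSite) -> np.ndarray:
        x, y = self.forward(site.longitude, site.latitude)
        return np.array([float(x), float(y)])


# ---------------------------------------------------------------------------
# inverse distance weighting
# ---------------------------------------------------------------------------

def idw_interpolate(
    query: np.ndarray,
    sample_xy: np.ndarray,
    values: np.ndarray,
    k: int = 5,
    p: float = 2.0,
) -> np.ndarray:
    """IDW over the ``k`` nearest samples; weights are d^-p (p = 2).

    An exact hit (zero distance) returns that sample's value. Samples tied
    with the k-th nearest distance are all included, so the result does not
    depend on input ordering.
    """
    sample_xy = np.asarray(sample_xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if sample_xy.shape[0] == 0:
        raise FieldUndefinedError("no samples to interpolate from")
    if k < 1:
        raise ValueError("k must be >= 1")
    query = np.asarray(query, dtype=float)
    d = np.hypot(sample_xy[:, 0] - query[0], sample_xy[:, 1] - query[1])
    hit = np.nonzero(d == 0.0)[0]
    if hit.size:
        return values[hit[0]].astype(float) if values.ndim > 1 else float(values[hit[0]])
    kk = min(k, d.size)
    cutoff = np.partition(d, kk - 1)[kk - 1]
    mask = d <= cutoff
    w = d[mask] ** (-p)
    w /= w.sum()
    if values.ndim > 1:
        return w @ values[mask]
    return float(w @ values[mask])


@dataclass
class SampleSet:
    """Per-radar samples for one (interval, band): points, vectors, scalars."""

    xy: np.ndarray  # (n, 2) projected km
    uv: np.ndarray  # (n, 2) m/s; rows meaningful only where has_vector
    rho: np.ndarray  # (n,) birds km^-3; meaningful only where has_density
    has_vector: np.ndarray  # (n,) bool
    has_density: np.ndarray  # (n,) bool
    radar_ids: tuple = ()

    @classmethod
    def empty(cls) -> "SampleSet":
        z = np.zeros((0, 2))
        return cls(z, z.copy(), np.zeros(0), np.zeros(0, bool), np.zeros(0, bool))

    @property
    def n_vector(self) -> int:
        return int(self.has_vector.sum())

    @property
    def n_density(self) -> int:
        return int(self.has_density.sum())


def interpolate_vector(
    point: np.ndarray, samples: SampleSet, k: int = 5, p: float = 2.0
) -> np.ndarray:
    """Interpolated (u, v) in m/s at a projected point."""
    m = samples.has_vector
    if not m.any():
        raise FieldUndefinedError("no vector-bearing samples")
    return idw_interpolate(point, samples.xy[m], samples.uv[m], k=k, p=p)


def interpolate_scalar(
    point: np.ndarray, samples: SampleSet, k: int = 5, p: float = 2.0
) -> float:
    """Interpolated bird density (birds km^-3) at a projected point."""
    m = samples.has_density
    if not m.any():
        raise FieldUndefinedError("no density-bearing samples")
    return idw_interpolate(point, samples.xy[m], samples.rho[m], k=k, p=p)


@dataclass
class FieldSnapshot:
    """Evaluable field of one time interval and band."""

    samples: SampleSet
    k: int = 5
    p: float = 2.0

    def velocity(self, point) -> np.ndarray:
        return interpolate_vector(np.asarray(point, float), self.samples, self.k, self.p)

    def density(self, point) -> float:
        return interpolate_scalar(np.asarray(point, float), self.samples, self.k, self.p)


class VectorField:
    """Time- and band-indexed migration velocity/density field.

    Piecewise-constant in time over aggregation intervals (each interval's
    sample set holds for [start, start + interval)); optional linear
    blending between consecutive intervals behind ``time_blend`` for
    smoother animation.
    """

    def __init__(
        self,
        snapshots: dict[tuple[int, int], SampleSet],
        t0: datetime,
        interval: timedelta,
        n_intervals: int,
        bands: Sequence[AltitudeBand],
        projection: AzimuthalEquidistant,
        k: int = 5,
        p: float = 2.0,
        time_blend: bool = False,
    ):
        if k < 1:
            raise ValueError("k must be >= 1")
        self._snapshots = snapshots
        self.t0 = ensure_utc(t0)
        self.interval = interval
        self.n_intervals = n_intervals
        self.bands = tuple(bands)
        self.projection = projection
        self.k = k
        self.p = p
        self.time_blend = time_blend

    # -- construction --------------------------------------------------------
    @classmethod
    def from_aggregates(
        cls,
        sites: Sequence[RadarSite],
        records: Iterable[AggregatedRecord],
        config: Optional[PreprocessConfig] = None,
        projection: Optional[AzimuthalEquidistant] = None,
        k: int = 5,
        p: float = 2.0,
        time_blend: bool = False,
    ) -> "VectorField":
        records = list(records)
        if not records:
            raise ValueError("no aggregated records")
        config = config or PreprocessConfig()
        projection = projection or AzimuthalEquidistant.for_sites(sites)
        site_xy = {s.radar_id: projection.project_site(s) for s in sites}
        bands = sorted({r.band for r in records}, key=lambda b: b.floor)
        band_index = {b: i for i, b in enumerate(bands)}
        starts = sorted({r.interval_start for r in records})
        t0 = starts[0]
        interval = timedelta(minutes=config.interval_minutes)
        n_intervals = int(round((starts[-1] - t0) / interval)) + 1

        grouped: dict[tuple[int, int], list[AggregatedRecord]] = {}
        for r in records:
            ti = int(round((r.interval_start - t0) / interval))
            grouped.setdefault((ti, band_index[r.band]), []).append(r)
        snapshots: dict[tuple[int, int], SampleSet] = {}
        for key, recs in grouped.items():
            xy = np.array([site_xy[r.radar_id] for r in recs])
            uv = np.array(
                [[r.u if r.u is not None else 0.0, r.v if r.v is not None else 0.0] for r in recs]
            )
            rho = np.array([r.density if r.density is not None else 0.0 for r in recs])
            has_vec = np.array([r.has_velocity for r in recs])
            has_rho = np.array([r.density is not None for r in recs])
            snapshots[key] = SampleSet(
                xy, uv, rho, has_vec, has_rho, tuple(r.radar_id for r in recs)
            )
        return cls(
            snapshots, t0, interval, n_intervals, bands, projection, k=k, p=p, time_blend=time_blend
        )

    # -- time handling -------------------------------------------------------
    @property
    def t_end(self) -> datetime:
        return self.t0 + self.interval * self.n_intervals

    def interval_index(self, t: datetime) -> int:
        t = ensure_utc(t)
        if not self.t0 <= t < self.t_end:
            raise TimeRangeError(
                f"{t.isoformat()} outside field range [{self.t0.isoformat()}, {self.t_end.isoformat()})"
            )
        return int((t - self.t0) // self.interval)

    def interval_starts(self) -> list[datetime]:
        return [self.t0 + i * self.interval for i in range(self.n_intervals)]

    def band_index(self, band: AltitudeBand) -> int:
        return self.bands.index(band)

    def sample_set(self, t: datetime, band: int | AltitudeBand) -> SampleSet:
        bi = band if isinstance(band, int) else self.band_index(band)
        return self._snapshots.get((self.interval_index(t), bi), SampleSet.empty())

    def at(self, t: datetime, band: int | AltitudeBand) -> FieldSnapshot:
        """Snapshot of the enclosing interval (piecewise-constant in time)."""
        return FieldSnapshot(self.sample_set(t, band), self.k, self.p)

    # -- evaluation ------------------------------------------------------------
    def velocity(self, point, t: datetime, band: int | AltitudeBand) -> np.ndarray:
        """(u, v) in m/s at a projected point and instant."""
        if not self.time_blend:
            return self.at(t, band).velocity(point)
        return self._blended(point, t, band, "velocity")

    def density(self, point, t: datetime, band: int | AltitudeBand) -> float:
        """Bird density (birds km^-3) at a projected point and instant."""
        if not self.time_blend:
            return self.at(t, band).density(point)
        return self._blended(point, t, band, "density")

    def _blended(self, point, t, band, what):
        t = ensure_utc(t)
        i = self.interval_index(t)
        frac = (t - (self.t0 + i * self.interval)) / self.interval
        a = getattr(self.at(self.t0 + i * self.interval, band), what)(point)
        if i + 1 >= self.n_intervals:
            return a
        try:
            b = getattr(self.at(self.t0 + (i + 1) * self.interval, band), what)(point)
        except FieldUndefinedError:
            return a
        return (1 - frac) * a + frac * b


def field_at(field: VectorField, t: datetime, band: int | AltitudeBand) -> FieldSnapshot:
    """Functional alias for :meth:`VectorField.at`."""
    return field.at(t, band)
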