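"""Filtering, unit conversion and temporal/altitudinal aggregation of profiles.

The pipeline mirrors the screening applied to operational weather-radar bird
profiles before visualization:

* reflectivity eta (cm^2 km^-3) is converted to bird density with an assumed
  per-bird radar cross section sigma (11 cm^2 for nocturnal passerine
  migration);
* the lowest altitude bin (0-200 m) is dropped to suppress ground clutter,
  and bins above the sampling ceiling are dropped;
* ground-speed components are only trusted where density is at least
  1 bird km^-3 — at lower densities the velocity estimate is easily
  contaminated by residual rain or insects — so sub-threshold velocities are
  cleared to missing (the density itself is kept);
* bins are averaged into altitude bands and 20-minute intervals. If a
  (radar, interval, band) group had measured velocities but none survived the
  density threshold, the aggregate velocity is set to (0, 0) and flagged:
  "measured, no migration detected". That zero is a datum and later pulls the
  interpolated field toward rest, unlike a missing velocity which is simply
  absent from interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .records import (
    AggregatedRecord,
    AltitudeBand,
    ProfileRecord,
    ValidationError,
    ensure_utc,
)

#: default altitude bands of the two-band flow visualization (m)
DEFAULT_BANDS = (AltitudeBand(200.0, 1600.0), AltitudeBand(1600.0, None))


@dataclass(frozen=True)
class PreprocessConfig:
    """Constants of the profile screening/aggregation pipeline.

    Parameters
    ----------
    cross_section
        sigma, assumed radar cross section per bird (cm^2). Default 11,
        the cross-calibrated value for nocturnal passerine migration.
    density_threshold
        Minimum rho_bird (birds km^-3) for which velocity is retained.
    bin_floor_min
        Bins with floor below this (m) are dropped (ground clutter).
    altitude_ceiling
        Sampling ceiling (m); bins at/above are dropped. 4000 m for the
        European 200-m-bin profiles, 3000 m for the US 100-m-bin profiles.
    interval_minutes
        Temporal aggregation window.
    scan_rounding_minutes
        Scan timestamps are rounded to the nearest multiple of this before
        windowing (US scans arrive on an irregular ~5-min cadence).
    bands
        Non-overlapping, sorted altitude bands for aggregation.
    bin_width
        Native altitude-bin depth (m); used by the synthetic generator.
    density_weighted
        If True, band velocity means are weighted by bin density. Off by
        default: the screening averages bins without weights.
    """

    cross_section: float = 11.0
    density_threshold: float = 1.0
    bin_floor_min: float = 200.0
    altitude_ceiling: float = 4000.0
    interval_minutes: int = 20
    scan_rounding_minutes: int = 5
    bands: tuple[AltitudeBand, ...] = DEFAULT_BANDS
    bin_width: float = 200.0
    density_weighted: bool = False

    def __post_init__(self) -> None:
        for name in (
            "cross_section",
            "density_threshold",
            "bin_floor_min",
            "altitude_ceiling",
            "interval_minutes",
            "scan_rounding_minutes",
            "bin_width",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        bands = tuple(self.bands)
        for a, b in zip(bands, bands[1:]):
            top = a.ceiling
            if top is None:
                raise ValidationError("only the last band may be open-ended")
            if b.floor < top:
                raise ValidationError(f"bands {a.label} and {b.label} overlap")
        object.__setattr__(self, "bands", bands)

    @classmethod
    def eu_default(cls) -> "PreprocessConfig":
        """EU-style profiles: 200-m bins up to 4000 m."""
        return cls()

    @classmethod
    def us_default(cls) -> "PreprocessConfig":
        """US-style (WSR-88D) profiles: 100-m bins up to 3000 m."""
        return cls(altitude_ceiling=3000.0, bin_width=100.0)

    def band_of(self, bin_floor: float) -> Optional[AltitudeBand]:
        """Band a bin belongs to, assigned by its floor; None if uncovered."""
        for band in self.bands:
            if band.contains(bin_floor):
                return band
        return None

    # -- flat key-value (de)serialization ------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cross_section": self.cross_section,
            "density_threshold": self.density_threshold,
            "bin_floor_min": self.bin_floor_min,
            "altitude_ceiling": self.altitude_ceiling,
            "interval_minutes": self.interval_minutes,
            "scan_rounding_minutes": self.scan_rounding_minutes,
            "bands": [b.label for b in self.bands],
            "bin_width": self.bin_width,
            "density_weighted": self.density_weighted,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(AltitudeBand.from_label(s) for s in d["bands"])
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PreprocessConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reflectivity_to_density(
    eta: float, config: PreprocessConfig = PreprocessConfig()
) -> float:
    """Convert reflectivity eta (cm^2 km^-3) to bird density (birds km^-3).

    rho_bird = eta / sigma with sigma the assumed per-bird cross section.
    """
    if eta < 0:
        raise ValidationError(f"reflectivity must be >= 0, got {eta}")
    return eta / config.cross_section


def filter_records(
    records: Iterable[ProfileRecord], config: PreprocessConfig = PreprocessConfig()
) -> list[ProfileRecord]:
    """Apply the altitude-range and density-threshold screening.

    Bins below ``bin_floor_min`` or at/above ``altitude_ceiling`` are
    dropped. Where density is missing or below ``density_threshold``, a
    measured velocity is cleared to missing (and the record marked, so that
    aggregation can apply the zero-velocity convention); the density is
    retained. The threshold is inclusive: density exactly at the threshold
    keeps its velocity.
    """
    out: list[ProfileRecord] = []
    for rec in records:
        if rec.bin_floor < config.bin_floor_min:
            continue
        if rec.bin_floor >= config.altitude_ceiling:
            continue
        below = rec.density is None or rec.density < config.density_threshold
        if below and rec.has_velocity:
            rec = replace(rec, u=None, v=None)
            rec.velocity_filtered = True
        out.append(rec)
    return out


def round_to_scan(ts: datetime, minutes: int) -> datetime:
    """Round a timestamp to the nearest ``minutes``-minute mark (half up)."""
    ts = ensure_utc(ts)
    step = minutes * 60
    epoch = ts.timestamp()
    return datetime.fromtimestamp(
        ((epoch + step / 2) // step) * step, tz=ts.tzinfo
    )


def interval_start(ts: datetime, interval_minutes: int) -> datetime:
    """Floor a timestamp onto the half-open window grid anchored at the hour."""
    ts = ensure_utc(ts)
    step = interval_minutes * 60
    return datetime.fromtimestamp((ts.timestamp() // step) * step, tz=ts.tzinfo)


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def aggregate(
    records: Iterable[Union[ProfileRecord, AggregatedRecord]],
    config: PreprocessConfig = PreprocessConfig(),
) -> list[AggregatedRecord]:
    """Average filtered bins into (radar, interval, band) aggregates.

    Density is the unweighted mean of all bins with a density, whether or
    not their velocity survived screening. Velocity is the unweighted mean
    over bins with a surviving velocity (density-weighted behind the
    ``density_weighted`` config flag); if none survived but at least one bin
    had a measured velocity, the aggregate is (0, 0) with the
    zero-convention flag; if no velocity was measured at all it is missing.

    Already-aggregated records are accepted (their band floor acts as the
    bin floor), making aggregation at unchanged intervals/bands idempotent.
    """
    groups: dict[tuple, list[ProfileRecord]] = {}
    for rec in records:
        if isinstance(rec, AggregatedRecord):
            bin_rec = ProfileRecord(
                radar_id=rec.radar_id,
                timestamp=rec.interval_start,
                bin_floor=rec.band.floor,
                bin_width=rec.band.depth_m(config.altitude_ceiling),
                density=rec.density,
                u=None if rec.velocity_is_zero_convention else rec.u,
                v=None if rec.velocity_is_zero_convention else rec.v,
            )
            bin_rec.velocity_filtered = rec.velocity_is_zero_convention
            rec = bin_rec
        band = config.band_of(rec.bin_floor)
        if band is None:
            continue
        t = round_to_scan(rec.timestamp, config.scan_rounding_minutes)
        t = interval_start(t, config.interval_minutes)
        groups.setdefault((rec.radar_id, t, band), []).append(rec)

    out: list[AggregatedRecord] = []
    for (radar_id, t, band), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2].floor)
    ):
        densities = [r.density for r in recs if r.density is not None]
        with_v = [r for r in recs if r.has_velocity]
        measured = bool(with_v) or any(r.velocity_filtered for r in recs)
        density = _mean(densities) if densities else None
        if with_v:
            if config.density_weighted:
                w = [r.density if r.density else 0.0 for r in with_v]
                tot = sum(w)
                if tot > 0:
                    u = sum(wi * r.u for wi, r in zip(w, with_v)) / tot
                    v = sum(wi * r.v for wi, r in zip(w, with_v)) / tot
                else:
                    u = _mean([r.u for r in with_v])
                    v = _mean([r.v for r in with_v])
            else:
                u = _mean([r.u for r in with_v])
                v = _mean([r.v for r in with_v])
            zero = False
        elif measured:
            u = v = 0.0
            zero = True
        else:
            u = v = None
            zero = False
        out.append(
            AggregatedRecord(
                radar_id=radar_id,
                interval_start=t,
                band=band,
                density=density,
                u=u,
                v=v,
                velocity_is_zero_convention=zero,
            )
        )
    return out


def preprocess(
    records: Iterable[ProfileRecord], config: PreprocessConfig = PreprocessConfig()
) -> list[AggregatedRecord]:
    """Screening + aggregation in one call."""
    return aggregate(filter_records(records, config), config)
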