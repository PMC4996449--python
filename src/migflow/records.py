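"""Domain records for radar bird-migration profiles.

A weather radar reports, every few minutes, a *vertical profile*: a stack of
altitude bins, each carrying a bird density aloft (``rho``, birds km^-3,
derived from reflectivity) and the horizontal ground-speed components of the
migrants (``u`` eastward, ``v`` northward, m s^-1). These records, their
aggregated per-altitude-band form, and the radar-site metadata are the common
currency of every module in this package.

Missing measurements are represented as ``None`` — never as zero. An
aggregate with ``u = v = 0`` and the ``velocity_is_zero_convention`` flag set
means "measurements were taken, but no migration was detected"; it is a real
datum and participates in field interpolation, unlike a missing velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional


class ValidationError(ValueError):
    """Input violates a domain invariant (bad coordinate, duplicate id...)."""


class SchemaError(ValidationError):
    """A delimited table does not carry the expected column set."""


class FormatError(ValueError):
    """A file could not be parsed as its declared format."""


def ensure_utc(ts: datetime) -> datetime:
    """Attach/convert to UTC; naive datetimes are taken to already be UTC."""
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def iso_z(ts: datetime) -> str:
    """ISO-8601 with trailing Z, second resolution."""
    return ensure_utc(ts).strftime("%Y-%m-%dT%H:%M:%SZ")


def parse_iso_z(text: str) -> datetime:
    return ensure_utc(datetime.fromisoformat(text.replace("Z", "+00:00")))


@dataclass(frozen=True)
class RadarSite:
    """One station of the radar network."""

    radar_id: str
    name: str
    longitude: float  # deg E
    latitude: float  # deg N

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"radar {self.radar_id!r}: longitude {self.longitude} out of [-180, 180]"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"radar {self.radar_id!r}: latitude {self.latitude} out of [-90, 90]"
            )


def check_unique_ids(sites: list[RadarSite]) -> None:
    seen: set[str] = set()
    for s in sites:
        if s.radar_id in seen:
            raise ValidationError(f"duplicate radar_id {s.radar_id!r}")
        seen.add(s.radar_id)


@dataclass(frozen=True)
class AltitudeBand:
    """Half-open altitude interval [floor, ceiling) in metres above surface.

    ``ceiling=None`` marks an open-ended top band (everything at or above
    ``floor``); its effective depth is resolved against the profile's
    sampling ceiling where a volume is needed.
    """

    floor: float
    ceiling: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ceiling is not None and not self.floor < self.ceiling:
            raise ValidationError(
                f"altitude band floor {self.floor} must be < ceiling {self.ceiling}"
            )

    def contains(self, altitude_m: float) -> bool:
        if altitude_m < self.floor:
            return False
        return self.ceiling is None or altitude_m < self.ceiling

    def depth_m(self, altitude_ceiling: float) -> float:
        top = self.ceiling if self.ceiling is not None else altitude_ceiling
        return min(top, altitude_ceiling) - self.floor

    @property
    def label(self) -> str:
        if self.ceiling is None:
            return f"{self.floor:g}+"
        return f"{self.floor:g}-{self.ceiling:g}"

    @classmethod
    def from_label(cls, label: str) -> "AltitudeBand":
        label = label.strip()
        try:
            if label.endswith("+"):
                return cls(float(label[:-1]), None)
            lo, hi = label.split("-")
            return cls(float(lo), float(hi))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"bad altitude band label {label!r}") from exc


@dataclass
class ProfileRecord:
    """One altitude bin of one radar scan (the raw table's row)."""

    radar_id: str
    timestamp: datetime
    bin_floor: float  # m above surface
    bin_width: float  # m
    density: Optional[float] = None  # birds km^-3
    u: Optional[float] = None  # m s^-1 eastward
    v: Optional[float] = None  # m s^-1 northward
    #: set by preprocess.filter_records when a measured velocity was cleared
    #: for failing the density threshold; internal, not part of any file dialect
    velocity_filtered: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.timestamp = ensure_utc(self.timestamp)
        if self.bin_width <= 0:
            raise ValidationError(f"bin_width must be > 0, got {self.bin_width}")
        if self.density is not None and self.density < 0:
            raise ValidationError(f"density must be >= 0, got {self.density}")
        if (self.u is None) != (self.v is None):
            raise ValidationError("u and v must be present or missing together")

    @property
    def has_velocity(self) -> bool:
        return self.u is not None


@dataclass
class AggregatedRecord:
    """Per (radar, 20-min interval, altitude band) mean density and velocity."""

    radar_id: str
    interval_start: datetime
    band: AltitudeBand
    density: Optional[float] = None
    u: Optional[float] = None
    v: Optional[float] = None
    velocity_is_zero_convention: bool = False

    def __post_init__(self) -> None:
        self.interval_start = ensure_utc(self.interval_start)
        if self.density is not None and self.density < 0:
            raise ValidationError(f"density must be >= 0, got {self.density}")
        if (self.u is None) != (self.v is None):
            raise ValidationError("u and v must be present or missing together")
        if self.velocity_is_zero_convention and not (self.u == 0.0 and self.v == 0.0):
            raise ValidationError("zero-velocity-convention record must have u = v = 0")

    @property
    def has_velocity(self) -> bool:
        return self.u is not None
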