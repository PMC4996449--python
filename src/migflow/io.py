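"""Readers/writers for the case-study file dialects.

A case study on disk is a directory holding:

* ``radars.json`` — array of ``{id, name, longitude, latitude}`` objects;
* ``birds.csv`` — the filtered/aggregated migration table, header
  ``radar_id,interval_start_time,altitude_band,avg_u_speed,avg_v_speed,avg_bird_density``;
* ``birds_raw.csv`` (optional) — the raw vertical-profile table, header
  ``radar_id,timestamp,bin_floor_m,bin_width_m,density,u,v``;
* ``basemap.topojson`` — TopoJSON (plain GeoJSON is accepted too);
* ``preprocess.json`` — the flat key-value form of
  :class:`~migflow.preprocess.PreprocessConfig`.

Missing measurements are empty CSV fields and round-trip as missing; a zero
is always a measured zero. Timestamps are ISO-8601 UTC with a trailing Z.

The TopoJSON codec is minimal but standard-conforming: quantized
(delta-encoded) and unquantized arcs, negative-index arc reversal, and the
usual geometry types. Geometries are returned as shapely objects in
longitude/latitude degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from shapely.geometry import LineString, MultiLineString, MultiPoint, MultiPolygon, Point, Polygon, shape
from shapely.geometry.base import BaseGeometry

from .preprocess import PreprocessConfig
from .records import (
    AggregatedRecord,
    AltitudeBand,
    FormatError,
    ProfileRecord,
    RadarSite,
    SchemaError,
    ValidationError,
    check_unique_ids,
    iso_z,
    parse_iso_z,
)

RAW_COLUMNS = ["radar_id", "timestamp", "bin_floor_m", "bin_width_m", "density", "u", "v"]
AGG_COLUMNS = [
    "radar_id",
    "interval_start_time",
    "altitude_band",
    "avg_u_speed",
    "avg_v_speed",
    "avg_bird_density",
]


# ---------------------------------------------------------------------------
# radar sites
# ---------------------------------------------------------------------------

def read_radar_sites(path: Union[str, Path]) -> list[RadarSite]:
    """Read ``radars.json``; order is preserved, ids must be unique."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise FormatError(f"{path}: expected a JSON array of site objects")
    sites = []
    for entry in raw:
        try:
            sites.append(
                RadarSite(
                    radar_id=str(entry["id"]),
                    name=str(entry.get("name", "")),
                    longitude=float(entry["longitude"]),
                    latitude=float(entry["latitude"]),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: site entry missing key {exc}") from exc
    check_unique_ids(sites)
    return sites


def write_radar_sites(sites: Sequence[RadarSite], path: Union[str, Path]) -> None:
    check_unique_ids(list(sites))
    payload = [
        {"id": s.radar_id, "name": s.name, "longitude": s.longitude, "latitude": s.latitude}
        for s in sites
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------

def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    """Exact float conversion with row-level errors (1-based file lines).

    Uses Python's float() rather than pandas' faster-but-lossy parser so
    that full-precision values survive a write/read round trip.
    """
    def conv_one(x):
        if pd.isna(x) or str(x).strip() == "":
            return None
        return float(x)

    out = []
    for i, x in enumerate(df[col]):
        try:
            out.append(conv_one(x))
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric {col} {x!r} at line {i + 2}"
            ) from None
    return pd.Series(out, dtype=object)


def read_profile_table(
    path: Union[str, Path], schema: str = "raw"
) -> list[Union[ProfileRecord, AggregatedRecord]]:
    """Read ``birds.csv`` in its ``raw`` or ``aggregated`` dialect.

    Empty fields become missing values (``None``), never zeros. Unknown
    column sets raise :class:`SchemaError` naming the missing columns.
    """
    if schema not in ("raw", "aggregated"):
        raise ValueError(f"schema must be 'raw' or 'aggregated', got {schema!r}")
    expected = RAW_COLUMNS if schema == "raw" else AGG_COLUMNS
    df = pd.read_csv(path, dtype=str, keep_default_na=True, skipinitialspace=True)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema!r}")

    def opt(x) -> Optional[float]:
        return None if pd.isna(x) else float(x)

    out: list[Union[ProfileRecord, AggregatedRecord]] = []
    if schema == "raw":
        dens = _numeric(df, "density", path)
        us = _numeric(df, "u", path)
        vs = _numeric(df, "v", path)
        floors = _numeric(df, "bin_floor_m", path)
        widths = _numeric(df, "bin_width_m", path)
        for i in range(len(df)):
            out.append(
                ProfileRecord(
                    radar_id=str(df["radar_id"].iloc[i]),
                    timestamp=parse_iso_z(df["timestamp"].iloc[i]),
                    bin_floor=float(floors.iloc[i]),
                    bin_width=float(widths.iloc[i]),
                    density=opt(dens.iloc[i]),
                    u=opt(us.iloc[i]),
                    v=opt(vs.iloc[i]),
                )
            )
    else:
        dens = _numeric(df, "avg_bird_density", path)
        us = _numeric(df, "avg_u_speed", path)
        vs = _numeric(df, "avg_v_speed", path)
        for i in range(len(df)):
            u, v = opt(us.iloc[i]), opt(vs.iloc[i])
            out.append(
                AggregatedRecord(
                    radar_id=str(df["radar_id"].iloc[i]),
                    interval_start=parse_iso_z(df["interval_start_time"].iloc[i]),
                    band=AltitudeBand.from_label(df["altitude_band"].iloc[i]),
                    density=opt(dens.iloc[i]),
                    u=u,
                    v=v,
                    # u = v = 0 is the "measured, no migration detected" datum
                    velocity_is_zero_convention=(u == 0.0 and v == 0.0),
                )
            )
    return out


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_profile_table(
    records: Sequence[Union[ProfileRecord, AggregatedRecord]],
    path: Union[str, Path],
) -> None:
    """Write records in the dialect matching their type (raw or aggregated)."""
    lines = []
    if records and isinstance(records[0], AggregatedRecord):
        lines.append(",".join(AGG_COLUMNS))
        for r in records:
            lines.append(
                ",".join(
                    [
                        r.radar_id,
                        iso_z(r.interval_start),
                        r.band.label,
                        _fmt(r.u),
                        _fmt(r.v),
                        _fmt(r.density),
                    ]
                )
            )
    else:
        lines.append(",".join(RAW_COLUMNS))
        for r in records:
            lines.append(
                ",".join(
                    [
                        r.radar_id,
                        iso_z(r.timestamp),
                        repr(float(r.bin_floor)),
                        repr(float(r.bin_width)),
                        _fmt(r.density),
                        _fmt(r.u),
                        _fmt(r.v),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# basemap (TopoJSON / GeoJSON)
# ---------------------------------------------------------------------------

@dataclass
class Basemap:
    """Geographic line/polygon features in lon/lat degrees."""

    features: list[BaseGeometry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def bounds(self) -> Optional[tuple[float, float, float, float]]:
        if not self.features:
            return None
        bs = [g.bounds for g in self.features]
        return (
            min(b[0] for b in bs),
            min(b[1] for b in bs),
            max(b[2] for b in bs),
            max(b[3] for b in bs),
        )


def _decode_arcs(topo: dict) -> list[list[tuple[float, float]]]:
    transform = topo.get("transform")
    arcs = []
    for arc in topo["arcs"]:
        if transform is not None:
            sx, sy = transform["scale"]
            tx, ty = transform["translate"]
            x = y = 0
            pts = []
            for dx, dy in arc:
                x += dx
                y += dy
                pts.append((x * sx + tx, y * sy + ty))
        else:
            pts = [(float(px), float(py)) for px, py in arc]
        arcs.append(pts)
    return arcs


def _arc_line(indices, arcs) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    for idx in indices:
        arc = arcs[~idx][::-1] if idx < 0 else arcs[idx]
        if pts and arc and pts[-1] == arc[0]:
            arc = arc[1:]
        pts.extend(arc)
    return pts


def _topo_geometry(obj: dict, arcs, out: list[BaseGeometry]) -> None:
    gtype = obj.get("type")
    if gtype is None:
        return
    if gtype == "GeometryCollection":
        for g in obj.get("geometries", []):
            _topo_geometry(g, arcs, out)
    elif gtype == "Point":
        out.append(Point(obj["coordinates"]))
    elif gtype == "MultiPoint":
        out.append(MultiPoint(obj["coordinates"]))
    elif gtype == "LineString":
        out.append(LineString(_arc_line(obj["arcs"], arcs)))
    elif gtype == "MultiLineString":
        out.append(MultiLineString([_arc_line(part, arcs) for part in obj["arcs"]]))
    elif gtype == "Polygon":
        out.append(Polygon(*[_arc_line(ring, arcs) for ring in obj["arcs"]][:1],
                           [_arc_line(ring, arcs) for ring in obj["arcs"]][1:]))
    elif gtype == "MultiPolygon":
        polys = []
        for poly in obj["arcs"]:
            rings = [_arc_line(ring, arcs) for ring in poly]
            polys.append(Polygon(rings[0], rings[1:]))
        out.append(MultiPolygon(polys))
    else:
        raise FormatError(f"unsupported TopoJSON geometry type {gtype!r}")


def read_basemap(path: Union[str, Path]) -> Basemap:
    """Read a TopoJSON or GeoJSON basemap into lon/lat shapely features."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "type" not in doc:
        raise FormatError(f"{path}: not a GeoJSON/TopoJSON document")
    features: list[BaseGeometry] = []
    if doc["type"] == "Topology":
        try:
            arcs = _decode_arcs(doc)
            for obj in doc.get("objects", {}).values():
                _topo_geometry(obj, arcs, features)
        except (KeyError, IndexError, TypeError) as exc:
            raise FormatError(f"{path}: malformed TopoJSON: {exc}") from exc
    elif doc["type"] == "FeatureCollection":
        try:
            for feat in doc.get("features", []):
                geom = feat.get("geometry")
                if geom is not None:
                    features.append(shape(geom))
        except Exception as exc:  # shapely raises a zoo of types here
            raise FormatError(f"{path}: malformed GeoJSON: {exc}") from exc
    else:
        try:
            features.append(shape(doc))
        except Exception as exc:
            raise FormatError(f"{path}: malformed GeoJSON geometry: {exc}") from exc
    return Basemap(features)


def write_basemap_geojson(basemap: Basemap, path: Union[str, Path]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": g.__geo_interface__}
            for g in basemap.features
        ],
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def _geom_to_topo(geom: BaseGeometry, arcs: list) -> dict:
    """Encode one geometry, appending its rings/lines to the arc table."""

    def add(coords) -> int:
        arcs.append([[float(x), float(y)] for x, y in coords])
        return len(arcs) - 1

    gi = geom.__geo_interface__
    gtype = gi["type"]
    if gtype == "Point":
        return {"type": "Point", "coordinates": list(gi["coordinates"])}
    if gtype == "MultiPoint":
        return {"type": "MultiPoint", "coordinates": [list(c) for c in gi["coordinates"]]}
    if gtype == "LineString":
        return {"type": "LineString", "arcs": [add(gi["coordinates"])]}
    if gtype == "MultiLineString":
        return {"type": "MultiLineString", "arcs": [[add(part)] for part in gi["coordinates"]]}
    if gtype == "Polygon":
        return {"type": "Polygon", "arcs": [[add(ring)] for ring in gi["coordinates"]]}
    if gtype == "MultiPolygon":
        return {
            "type": "MultiPolygon",
            "arcs": [[[add(ring)] for ring in poly] for poly in gi["coordinates"]],
        }
    raise FormatError(f"cannot encode geometry type {gtype!r} as TopoJSON")


def write_basemap_topojson(basemap: Basemap, path: Union[str, Path]) -> None:
    """Write an unquantized TopoJSON (absolute arc coordinates, lossless)."""
    arcs: list = []
    geoms = [_geom_to_topo(g, arcs) for g in basemap.features]
    doc = {
        "type": "Topology",
        "objects": {"basemap": {"type": "GeometryCollection", "geometries": geoms}},
        "arcs": arcs,
    }
    Path(path).write_text(json.dumps(doc) + "\n")


# ---------------------------------------------------------------------------
# case-study bundle
# ---------------------------------------------------------------------------

@dataclass
class CaseStudy:
    """Everything needed to visualize one migration case."""

    sites: list[RadarSite]
    records: list[AggregatedRecord]
    basemap: Basemap = field(default_factory=Basemap)
    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    raw_records: Optional[list[ProfileRecord]] = None

    def __post_init__(self) -> None:
        ids = {s.radar_id for s in self.sites}
        for rec in self.records:
            if rec.radar_id not in ids:
                raise ValidationError(
                    f"record references unknown radar_id {rec.radar_id!r}"
                )

    def site(self, radar_id: str) -> RadarSite:
        for s in self.sites:
            if s.radar_id == radar_id:
                return s
        raise KeyError(radar_id)


def save_case(case: CaseStudy, directory: Union[str, Path]) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_radar_sites(case.sites, d / "radars.json")
    write_profile_table(case.records, d / "birds.csv")
    if case.raw_records is not None:
        write_profile_table(case.raw_records, d / "birds_raw.csv")
    write_basemap_topojson(case.basemap, d / "basemap.topojson")
    case.config.save(d / "preprocess.json")


def load_case(directory: Union[str, Path]) -> CaseStudy:
    """Load a case-study directory written by :func:`save_case` / the CLI."""
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"case directory {d} does not exist")
    sites = read_radar_sites(d / "radars.json")
    records = read_profile_table(d / "birds.csv", schema="aggregated")
    basemap = Basemap()
    for name in ("basemap.topojson", "basemap.geojson", "basemap.json"):
        if (d / name).exists():
            basemap = read_basemap(d / name)
            break
    config = PreprocessConfig()
    if (d / "preprocess.json").exists():
        config = PreprocessConfig.load(d / "preprocess.json")
    raw = None
    if (d / "birds_raw.csv").exists():
        raw = read_profile_table(d / "birds_raw.csv", schema="raw")
    return CaseStudy(sites=sites, records=records, basemap=basemap, config=config, raw_records=raw)
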