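"""Headless raster rendering: streamlet animations and TIMAMP maps.

The flow engine and TIMAMP work in projected km; this module is the only
place where km are mapped to pixels. Frames are rasterized with the Agg
backend and written as animated GIF (or a single PNG), so renders are
reproducible byte for byte for a given seed and style.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

import imageio.v2 as imageio
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.collections import LineCollection

from . import streamlets as sl
from .field import AzimuthalEquidistant, VectorField
from .io import CaseStudy
from .records import ValidationError
from .timamp import TimampConfig, TimampResult, run_timamp

#: one colour per altitude stratum, low to high
BAND_COLORS = ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628")


@dataclass(frozen=True)
class RenderStyle:
    """Canvas geometry and colours."""

    width_px: int = 720
    height_px: int = 600
    dpi: int = 100
    background: str = "#101020"
    basemap_color: str = "#3a3a55"
    radar_color: str = "#000000"
    radar_radius_pt: float = 4.0
    streamlet_color: str = "#9fd8ff"
    band_colors: tuple = BAND_COLORS
    margin_km: float = 30.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.dpi <= 0:
            raise ValidationError("canvas dimensions must be positive")

    def color_for_band(self, index: int) -> str:
        return self.band_colors[index % len(self.band_colors)]


def _domain_km(
    case: CaseStudy, projection: AzimuthalEquidistant, margin_km: float
) -> tuple[float, float, float, float]:
    xs, ys = [], []
    for s in case.sites:
        x, y = projection.project_site(s)
        xs.append(x)
        ys.append(y)
    b = case.basemap.bounds()
    if b is not None:
        for lon, lat in ((b[0], b[1]), (b[2], b[3])):
            x, y = projection.forward(lon, lat)
            xs.append(float(x))
            ys.append(float(y))
    return (min(xs) - margin_km, max(xs) + margin_km, min(ys) - margin_km, max(ys) + margin_km)


def _new_axes(style: RenderStyle, domain, background: str):
    fig = plt.figure(
        figsize=(style.width_px / style.dpi, style.height_px / style.dpi), dpi=style.dpi
    )
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_facecolor(background)
    fig.patch.set_facecolor(background)
    ax.set_xlim(domain[0], domain[1])
    ax.set_ylim(domain[2], domain[3])
    ax.set_aspect("equal")
    ax.axis("off")
    return fig, ax


def _draw_base(ax, case: CaseStudy, projection, style: RenderStyle, radar_color=None):
    for geom in case.basemap.features:
        gi = geom.__geo_interface__
        parts = []
        gtype = gi["type"]
        if gtype == "LineString":
            parts = [gi["coordinates"]]
        elif gtype == "MultiLineString":
            parts = list(gi["coordinates"])
        elif gtype == "Polygon":
            parts = list(gi["coordinates"])
        elif gtype == "MultiPolygon":
            parts = [ring for poly in gi["coordinates"] for ring in poly]
        for part in parts:
            arr = np.asarray(part, dtype=float)
            x, y = projection.forward(arr[:, 0], arr[:, 1])
            ax.plot(x, y, color=style.basemap_color, linewidth=0.8)
    for s in case.sites:
        x, y = projection.project_site(s)
        ax.plot(
            [x], [y],
            marker="o",
            markersize=style.radar_radius_pt,
            color=radar_color or style.radar_color,
            linestyle="none",
        )


def _rasterize(fig) -> np.ndarray:
    canvas = FigureCanvasAgg(fig)
    canvas.draw()
    buf = np.asarray(canvas.buffer_rgba())
    return buf[:, :, :3].copy()


def render_flow(
    case: CaseStudy,
    band: int = 0,
    start: Optional[datetime] = None,
    n_frames: int = 60,
    style: RenderStyle = RenderStyle(),
    out_path: Union[str, Path] = "flow.gif",
    seed: Optional[int] = 0,
    n_streamlets: int = sl.DEFAULT_POPULATION,
    frames_per_interval: int = 120,
    fps: int = 30,
    field: Optional[VectorField] = None,
) -> Path:
    """Render the animated streamlet visualization to a GIF (or PNG).

    Radar sites are drawn as filled circles on the basemap; streamlet
    trails fade with age. ``.gif`` gets all frames animated; ``.png`` gets
    the last frame only.
    """
    out_path = Path(out_path)
    if field is None:
        field = VectorField.from_aggregates(case.sites, case.records, config=case.config)
    projection = field.projection
    domain = _domain_km(case, projection, style.margin_km)
    state = sl.seed(
        domain,
        n=n_streamlets,
        seed=seed,
        band=band,
        start_time=start or field.t0,
        frames_per_interval=frames_per_interval,
    )
    frames = []
    for _ in range(n_frames):
        sl.step(state, field)
        fig, ax = _new_axes(style, domain, style.background)
        _draw_base(ax, case, projection, style, radar_color="#dddddd")
        segments, colors = [], []
        base = matplotlib.colors.to_rgb(style.streamlet_color)
        for poly, opac in sl.frame_geometry(state):
            for i in range(len(poly) - 1):
                segments.append(poly[i : i + 2])
                colors.append((*base, float(opac[i])))
        if segments:
            ax.add_collection(LineCollection(segments, colors=colors, linewidths=1.2))
        frames.append(_rasterize(fig))
        plt.close(fig)
    if out_path.suffix.lower() == ".png":
        imageio.imwrite(out_path, frames[-1])
    elif out_path.suffix.lower() == ".gif":
        imageio.mimwrite(out_path, frames, duration=1000.0 / fps, loop=0)
    else:
        raise ValidationError(
            f"unsupported animation format {out_path.suffix!r} (use .gif or .png)"
        )
    return out_path


def render_timamp(
    case: CaseStudy,
    config: TimampConfig,
    style: RenderStyle = RenderStyle(background="#ffffff", basemap_color="#bbbbbb"),
    out_path: Union[str, Path] = "timamp.png",
    result: Optional[TimampResult] = None,
) -> tuple[Path, TimampResult]:
    """Render a TIMAMP pathline map to a static PNG.

    One colour per altitude stratum; line thickness follows interpolated
    density along each pathline and a dot marks each temporal endpoint. The
    legend states the window and the migrants-per-path count.
    """
    out_path = Path(out_path)
    if result is None:
        result = run_timamp(case, config)
    projection = result.field.projection
    domain = _domain_km(case, projection, style.margin_km)
    fig, ax = _new_axes(style, domain, style.background)
    _draw_base(ax, case, projection, style)
    for sp in result.pathlines:
        color = style.color_for_band(sp.pathline.anchor.band_index)
        curve = sp.curve
        if len(curve) > 1:
            segs = np.stack([curve[:-1], curve[1:]], axis=1)
            widths = 0.5 * (sp.thickness[:-1] + sp.thickness[1:])
            ax.add_collection(
                LineCollection(segs, colors=color, linewidths=widths, alpha=0.8, capstyle="round")
            )
        ax.plot(
            [sp.endpoint[0]], [sp.endpoint[1]],
            marker="o", markersize=2.5, color=color, linestyle="none",
        )
    legend = (
        f"{config.window_start.strftime('%Y-%m-%d %H:%MZ')} + {config.duration_hours} h   "
        f"{config.migrants_per_path:,} migrants/path   {config.strata_count} strata"
    )
    ax.text(
        0.01, 0.01, legend, transform=ax.transAxes, fontsize=7, color="#333333",
        verticalalignment="bottom",
    )
    imageio.imwrite(out_path, _rasterize(fig))
    plt.close(fig)
    return out_path, result
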