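"""Visual-channel resolution: columns -> positions, colors and radii.

A :class:`ChannelMapping` declares which measurement drives each channel
(x, y, optionally color and size).  :func:`make_render_spec` resolves it
against a table into a :class:`RenderSpec` — the fully specified per-point
plot behind both the PNG and the self-contained HTML export.

Color uses a continuous blue-green-red scale: the lowest value of the color
column is pure blue, the midpoint pure green and the highest pure red, with
each RGB component piecewise-linear in the value.  Size is a linear radius
ramp clamped to [r_min, r_max].  Points with a missing value in any mapped
channel are excluded and counted; retained + excluded always equals the
number of table rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyPlotError, MappingError, ScaleError
from .io import OmicsTable

__all__ = [
    "ChannelMapping",
    "ColorScale",
    "RenderSpec",
    "RenderPoint",
    "AxisRanges",
    "Legend",
    "map_color",
    "map_size",
    "make_render_spec",
    "export_png",
    "export_html",
    "parse_embedded_points",
    "DEFAULT_R_MIN",
    "DEFAULT_R_MAX",
]

DEFAULT_R_MIN = 3.0
DEFAULT_R_MAX = 12.0
DEFAULT_GREY = (128, 128, 128)

BLUE = (0, 0, 255)
GREEN = (0, 255, 0)
RED = (255, 0, 0)


@dataclass(frozen=True)
class ChannelMapping:
    """Declarative binding of measurement columns to visual channels.

    ``x`` and ``y`` are required; ``color`` and ``size`` are optional.
    ``x_log``/``y_log`` apply a log10 transform before range computation;
    non-positive values become missing under log.
    """

    x: str
    y: str
    color: str | None = None
    size: str | None = None
    x_log: bool = False
    y_log: bool = False

    def columns(self) -> list[str]:
        cols = [self.x, self.y]
        if self.color is not None:
            cols.append(self.color)
        if self.size is not None:
            cols.append(self.size)
        return cols


class ColorScale:
    """Blue -> green -> red piecewise-linear RGB ramp on [v_min, v_max]."""

    __slots__ = ("v_min", "v_max")

    def __init__(self, v_min: float, v_max: float):
        if not (v_min < v_max):
            raise ScaleError(f"color scale needs v_min < v_max, got [{v_min}, {v_max}]")
        self.v_min = float(v_min)
        self.v_max = float(v_max)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.v_min + self.v_max)


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5).astype(int)


def _map_colors(values: np.ndarray, scale: ColorScale) -> np.ndarray:
    """Vectorized blue-green-red mapping; returns an (n, 3) int array."""
    v = np.clip(np.asarray(values, dtype=float), scale.v_min, scale.v_max)
    half = scale.midpoint - scale.v_min
    t = (v - scale.v_min) / half  # 0..2 across the full range
    low = t <= 1.0
    r = np.where(low, 0.0, (t - 1.0) * 255.0)
    g = np.where(low, t * 255.0, (2.0 - t) * 255.0)
    b = np.where(low, (1.0 - t) * 255.0, 0.0)
    return _round_half_up(np.stack([r, g, b], axis=-1))


def map_color(value: float, scale: ColorScale) -> tuple[int, int, int]:
    """Map one finite value to an RGB triple on the blue-green-red scale.

    Values at or below ``v_min`` are blue (0,0,255), at or above ``v_max``
    red (255,0,0), and the midpoint is green (0,255,0); components are
    rounded half-up.
    """
    if not math.isfinite(value):
        raise ScaleError(f"cannot map non-finite value {value!r} to a color")
    r, g, b = _map_colors(np.array([value]), scale)[0]
    return int(r), int(g), int(b)


def map_size(
    value: float, v_min: float, v_max: float, r_min: float = DEFAULT_R_MIN, r_max: float = DEFAULT_R_MAX
) -> float:
    """Linear radius ramp on [v_min, v_max], clamped to [r_min, r_max]."""
    if not (v_min < v_max):
        raise ScaleError(f"size scale needs v_min < v_max, got [{v_min}, {v_max}]")
    if not (0 < r_min <= r_max):
        raise ScaleError(f"radii must satisfy 0 < r_min <= r_max, got [{r_min}, {r_max}]")
    t = (value - v_min) / (v_max - v_min)
    return float(r_min + min(max(t, 0.0), 1.0) * (r_max - r_min))


@dataclass(frozen=True)
class RenderPoint:
    gene_id: str
    x_data: float
    y_data: float
    x_canvas: float
    y_canvas: float
    rgb: tuple[int, int, int]
    radius: float


@dataclass(frozen=True)
class AxisRanges:
    x_min: float
    x_max: float
    y_min: float
    y_max: float


@dataclass(frozen=True)
class Legend:
    color_column: str | None = None
    color_min: float | None = None
    color_max: float | None = None
    size_column: str | None = None
    size_min: float | None = None
    size_max: float | None = None


@dataclass(frozen=True)
class RenderSpec:
    """A fully resolved per-point plot description."""

    points: tuple[RenderPoint, ...]
    canvas_width: int
    canvas_height: int
    axis_ranges: AxisRanges
    legend: Legend
    n_excluded: int

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ResolvedChannels:
    """Per-row channel values after log transforms, plus the retained mask."""

    x: np.ndarray
    y: np.ndarray
    color: np.ndarray | None
    size: np.ndarray | None
    retained: np.ndarray  # boolean, True where no mapped channel is missing


def resolve_channels(table: OmicsTable, mapping: ChannelMapping) -> ResolvedChannels:
    """Validate a mapping against a table and pull out the channel arrays."""
    for col in mapping.columns():
        if col not in table.measurement_names:
            raise MappingError(
                f"unknown measurement {col!r}; available: {table.measurement_names}"
            )
    x = table.column(mapping.x).astype(float)
    y = table.column(mapping.y).astype(float)
    if mapping.x_log:
        x = _log10_or_nan(x)
    if mapping.y_log:
        y = _log10_or_nan(y)
    color = table.column(mapping.color).astype(float) if mapping.color else None
    size = table.column(mapping.size).astype(float) if mapping.size else None
    retained = np.isfinite(x) & np.isfinite(y)
    if color is not None:
        retained &= np.isfinite(color)
    if size is not None:
        retained &= np.isfinite(size)
    return ResolvedChannels(x=x, y=y, color=color, size=size, retained=retained)


def _log10_or_nan(values: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan)
    positive = values > 0
    out[positive] = np.log10(values[positive])
    return out


def _padded_range(values: np.ndarray, pad_frac: float = 0.05) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:  # degenerate: all points share the value
        return lo - 0.5, hi + 0.5
    pad = pad_frac * (hi - lo)
    return lo - pad, hi + pad


def _observed_range(values: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        return lo - 0.5, hi + 0.5
    return lo, hi


def make_render_spec(
    table: OmicsTable,
    mapping: ChannelMapping,
    canvas_width: int = 800,
    canvas_height: int = 600,
    margin: int = 40,
    r_min: float = DEFAULT_R_MIN,
    r_max: float = DEFAULT_R_MAX,
    color_range: tuple[float, float] | None = None,
    size_range: tuple[float, float] | None = None,
) -> RenderSpec:
    """Resolve ``mapping`` against ``table`` into a per-point render spec.

    Axis ranges are the min/max of the mapped x and y over retained points,
    expanded by 5% padding.  The screen convention applies: x_canvas grows
    with x_data, y_canvas shrinks as y_data grows (origin top-left).  Colors
    come from :func:`map_color` over the color column's observed min/max
    (override with ``color_range``); radii likewise from :func:`map_size`.
    Without a color column every point is mid-grey; without a size column
    every radius is ``r_min``.  Later points paint over earlier ones.
    """
    if canvas_width <= 0 or canvas_height <= 0:
        raise ScaleError(f"canvas must be positive, got {canvas_width}x{canvas_height}")
    if margin < 0 or 2 * margin >= min(canvas_width, canvas_height):
        raise ScaleError(f"margin {margin} leaves no plot area on a {canvas_width}x{canvas_height} canvas")

    resolved = resolve_channels(table, mapping)
    keep = resolved.retained
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise EmptyPlotError("no point has complete values for the mapped channels")

    xs, ys = resolved.x[keep], resolved.y[keep]
    x_min, x_max = _padded_range(xs)
    y_min, y_max = _padded_range(ys)

    plot_w = canvas_width - 2 * margin
    plot_h = canvas_height - 2 * margin
    x_canvas = margin + (xs - x_min) / (x_max - x_min) * plot_w
    y_canvas = canvas_height - margin - (ys - y_min) / (y_max - y_min) * plot_h

    legend_kwargs: dict = {}
    if resolved.color is not None:
        cvals = resolved.color[keep]
        c_lo, c_hi = color_range if color_range is not None else _observed_range(cvals)
        scale = ColorScale(c_lo, c_hi)
        rgbs = _map_colors(cvals, scale)
        legend_kwargs.update(color_column=mapping.color, color_min=c_lo, color_max=c_hi)
    else:
        rgbs = np.tile(np.array(DEFAULT_GREY), (len(xs), 1))

    if resolved.size is not None:
        svals = resolved.size[keep]
        s_lo, s_hi = size_range if size_range is not None else _observed_range(svals)
        radii = [map_size(v, s_lo, s_hi, r_min, r_max) for v in svals]
        legend_kwargs.update(size_column=mapping.size, size_min=s_lo, size_max=s_hi)
    else:
        radii = [float(r_min)] * len(xs)

    gene_ids = np.asarray(table.gene_ids, dtype=object)[keep]
    points = tuple(
        RenderPoint(
            gene_id=str(g),
            x_data=float(xd),
            y_data=float(yd),
            x_canvas=float(xc),
            y_canvas=float(yc),
            rgb=(int(c[0]), int(c[1]), int(c[2])),
            radius=float(r),
        )
        for g, xd, yd, xc, yc, c, r in zip(gene_ids, xs, ys, x_canvas, y_canvas, rgbs, radii)
    )
    return RenderSpec(
        points=points,
        canvas_width=canvas_width,
        canvas_height=canvas_height,
        axis_ranges=AxisRanges(x_min, x_max, y_min, y_max),
        legend=Legend(**legend_kwargs),
        n_excluded=n_excluded,
    )


def export_png(spec: RenderSpec, sink) -> None:
    """Rasterize the spec: white background, one filled circle per point.

    Points are painted in list order, so later points cover earlier ones.
    """
    from PIL import Image, ImageDraw

    if spec.canvas_width <= 0 or spec.canvas_height <= 0:
        raise ScaleError("cannot render a zero-sized canvas")
    image = Image.new("RGB", (spec.canvas_width, spec.canvas_height), (255, 255, 255))
    draw = ImageDraw.Draw(image)
    for p in spec.points:
        x, y, r = p.x_canvas, p.y_canvas, p.radius
        draw.ellipse([x - r, y - r, x + r, y + r], fill=p.rgb)
    image.save(sink, format="PNG")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>$title</title>
</head>
<body>
<canvas id="plot" width="$width" height="$height" style="border:1px solid #ccc"></canvas>
<!-- POINT-DATA-BEGIN -->
<script type="application/json" id="point-data">$payload</script>
<!-- POINT-DATA-END -->
<script>
(function () {
  var spec = JSON.parse(document.getElementById("point-data").textContent);
  var ctx = document.getElementById("plot").getContext("2d");
  ctx.fillStyle = "#ffffff";
  ctx.fillRect(0, 0, spec.canvas_width, spec.canvas_height);
  spec.points.forEach(function (p) {
    ctx.beginPath();
    ctx.arc(p.x_canvas, p.y_canvas, p.radius, 0, 2 * Math.PI);
    ctx.fillStyle = "rgb(" + p.rgb.join(",") + ")";
    ctx.fill();
  });
})();
</script>
</body>
</html>
"""

_DATA_BEGIN = "<!-- POINT-DATA-BEGIN -->"
_DATA_END = "<!-- POINT-DATA-END -->"


def export_html(spec: RenderSpec, sink, title: str = "scattergate plot") -> None:
    """Write a single self-contained HTML document with a canvas renderer.

    The full point data is embedded as a JSON literal between the marker
    comments ``POINT-DATA-BEGIN``/``POINT-DATA-END`` so a test harness (or
    :func:`parse_embedded_points`) can recover it exactly.
    """
    from string import Template

    payload = json.dumps(_spec_to_jsonable(spec), separators=(",", ":"), sort_keys=True)
    document = Template(_HTML_TEMPLATE).substitute(
        title=title, width=spec.canvas_width, height=spec.canvas_height, payload=payload
    )
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(document)
    else:
        sink.write(document)


def _spec_to_jsonable(spec: RenderSpec) -> dict:
    return {
        "canvas_width": spec.canvas_width,
        "canvas_height": spec.canvas_height,
        "n_excluded": spec.n_excluded,
        "axis_ranges": {
            "x_min": spec.axis_ranges.x_min,
            "x_max": spec.axis_ranges.x_max,
            "y_min": spec.axis_ranges.y_min,
            "y_max": spec.axis_ranges.y_max,
        },
        "legend": {
            "color_column": spec.legend.color_column,
            "color_min": spec.legend.color_min,
            "color_max": spec.legend.color_max,
            "size_column": spec.legend.size_column,
            "size_min": spec.legend.size_min,
            "size_max": spec.legend.size_max,
        },
        "points": [
            {
                "gene_id": p.gene_id,
                "x_data": p.x_data,
                "y_data": p.y_data,
                "x_canvas": p.x_canvas,
                "y_canvas": p.y_canvas,
                "rgb": list(p.rgb),
                "radius": p.radius,
            }
            for p in spec.points
        ],
    }


def parse_embedded_points(document: str) -> dict:
    """Recover the JSON payload embedded by :func:`export_html`."""
    start = document.index(_DATA_BEGIN)
    end = document.index(_DATA_END, start)
    block = document[start + len(_DATA_BEGIN) : end]
    open_tag = block.index(">", block.index("<script")) + 1
    close_tag = block.index("</script>")
    return json.loads(block[open_tag:close_tag])
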