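"""Deterministic static renderings of the arc views, heat maps and line
plots.

Instead of an interactive canvas, every view is built as a
:class:`Scene` — an ordered list of geometric primitives — and serialized
to SVG with fixed float formatting, so identical inputs always produce
byte-identical output.  The same primitives can be rasterized to PNG
through matplotlib.

View semantics shared by all arc views: arc stroke width (2D) or apex
height (3D) is proportional to the connection weight (gene count);
directed arcs take the palette color of the *target* phenotype — the
phenotype transitioned into — while undirected arcs use a single
connection color; default arc transparency is 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataValueError, FormatError, UnknownEntityError
from .events import ConnectionSet
from .io import BarSeries, PhenoDataset
from .lanes import LaneOrdering
from .profiles import ClusterResult

# ---------------------------------------------------------------------------
# palettes (qualitative ColorBrewer-style schemes + colorblind-safe Okabe-Ito)

PALETTES: dict[str, list[str]] = {
    "set1": [
        "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
        "#ffff33", "#a65628", "#f781bf", "#999999",
    ],
    "dark2": [
        "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
        "#e6ab02", "#a6761d", "#666666",
    ],
    "paired": [
        "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99", "#e31a1c",
        "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
    ],
    "colorblind": [  # Okabe-Ito
        "#e69f00", "#56b4e9", "#009e73", "#f0e442", "#0072b2",
        "#d55e00", "#cc79a7", "#000000",
    ],
}

SINGLE_COLOR = "#4477aa"


def palette(scheme: str, n: int) -> list[str]:
    """Return ``n`` colors: pairwise distinct for qualitative schemes
    (error beyond scheme capacity), ``n`` copies of one color for
    ``"single"``.  Assignment is stable by index."""
    if n < 1:
        raise DataValueError("palette size must be >= 1")
    if scheme == "single":
        return [SINGLE_COLOR] * n
    if scheme not in PALETTES:
        raise DataValueError(
            f"unknown palette {scheme!r}; available: "
            f"{sorted(PALETTES)} or 'single'"
        )
    colors = PALETTES[scheme]
    if n > len(colors):
        raise DataValueError(
            f"palette {scheme!r} holds {len(colors)} colors, {n} requested; "
            f"use scheme 'single' for large lane counts"
        )
    return colors[:n]


def diverging_color(t: float) -> str:
    """Blue-white-red diverging map for heat maps; ``t`` in [0, 1]."""
    t = min(max(t, 0.0), 1.0)
    lo, mid, hi = (33, 102, 172), (247, 247, 247), (178, 24, 43)
    if t < 0.5:
        f = t / 0.5
        rgb = tuple(round(a + (b - a) * f) for a, b in zip(lo, mid))
    else:
        f = (t - 0.5) / 0.5
        rgb = tuple(round(a + (b - a) * f) for a, b in zip(mid, hi))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


# ---------------------------------------------------------------------------
# scene model


@dataclass(frozen=True)
class Element:
    """One drawable primitive.

    ``tag`` is the SVG tag (path, line, rect, circle, polyline, text);
    ``kind`` is the semantic role (arc, lane, segment, cell, series, bar,
    tick, label) used for element-count audits; ``attrs`` hold numeric or
    string attribute values formatted only at serialization time; ``meta``
    carries audit data (weight, apex height) exported as ``data-*``
    attributes.
    """

    tag: str
    kind: str
    attrs: tuple[tuple[str, object], ...]
    text: str | None = None
    meta: tuple[tuple[str, object], ...] = ()


def _f(v: object) -> str:
    if isinstance(v, float):
        return f"{v:.4f}"
    return str(v)


@dataclass
class Scene:
    """An ordered collection of primitives with a fixed canvas size."""

    width: float
    height: float
    elements: list[Element] = field(default_factory=list)

    def add(self, tag: str, kind: str, text: str | None = None, meta: dict | None = None, **attrs) -> None:
        self.elements.append(
            Element(
                tag,
                kind,
                tuple(attrs.items()),
                text,
                tuple((meta or {}).items()),
            )
        )

    def count(self, kind: str) -> int:
        return sum(1 for e in self.elements if e.kind == kind)

    def to_svg(self) -> str:
        out = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(self.width)}" '
            f'height="{_f(self.height)}" viewBox="0 0 {_f(self.width)} {_f(self.height)}">',
        ]
        for e in self.elements:
            parts = [f"<{e.tag}"]
            parts.append(f' data-kind="{e.kind}"')
            for k, v in e.attrs:
                parts.append(f' {k.replace("_", "-")}="{_f(v)}"')
            for k, v in e.meta:
                parts.append(f' data-{k.replace("_", "-")}="{_f(v)}"')
            if e.text is None:
                parts.append("/>")
            else:
                parts.append(f">{e.text}</{e.tag}>")
            out.append("".join(parts))
        out.append("</svg>")
        return "\n".join(out) + "\n"

    def to_png(self, path: str, dpi: int = 100) -> None:
        """Rasterize through matplotlib (Agg)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle as MplCircle
        from matplotlib.patches import Rectangle
        from matplotlib.path import Path as MplPath
        import matplotlib.patches as mpatches

        fig, ax = plt.subplots(figsize=(self.width / dpi, self.height / dpi), dpi=dpi)
        ax.set_xlim(0, self.width)
        ax.set_ylim(self.height, 0)  # SVG y grows downward
        ax.axis("off")
        for e in self.elements:
            a = dict(e.attrs)
            alpha = float(a.get("opacity", 1.0))
            if e.tag == "line":
                ax.plot(
                    [a["x1"], a["x2"]], [a["y1"], a["y2"]],
                    color=a.get("stroke", "#000000"),
                    linewidth=float(a.get("stroke_width", 1.0)),
                    alpha=alpha,
                )
            elif e.tag == "path":
                verts, codes = _parse_path(str(a["d"]))
                patch = mpatches.PathPatch(
                    MplPath(verts, codes),
                    fill=False,
                    edgecolor=a.get("stroke", "#000000"),
                    linewidth=float(a.get("stroke_width", 1.0)),
                    alpha=alpha,
                )
                ax.add_patch(patch)
            elif e.tag == "rect":
                ax.add_patch(
                    Rectangle(
                        (float(a["x"]), float(a["y"])),
                        float(a["width"]), float(a["height"]),
                        facecolor=a.get("fill", "#000000"),
                        edgecolor=a.get("stroke", "none"),
                        alpha=alpha,
                    )
                )
            elif e.tag == "circle":
                ax.add_patch(
                    MplCircle(
                        (float(a["cx"]), float(a["cy"])), float(a["r"]),
                        facecolor=a.get("fill", "#000000"), alpha=alpha,
                    )
                )
            elif e.tag == "polyline":
                pts = [
                    tuple(map(float, p.split(",")))
                    for p in str(a["points"]).split()
                ]
                xs, ys = zip(*pts)
                ax.plot(
                    xs, ys,
                    color=a.get("stroke", "#000000"),
                    linewidth=float(a.get("stroke_width", 1.0)),
                    alpha=alpha,
                )
            elif e.tag == "text":
                ax.text(
                    float(a["x"]), float(a["y"]), e.text or "",
                    fontsize=float(a.get("font_size", 10)),
                    color=a.get("fill", "#000000"),
                    ha={"middle": "center", "end": "right"}.get(
                        str(a.get("text_anchor", "start")), "left"
                    ),
                )
        fig.savefig(path, dpi=dpi)
        plt.close(fig)


def _parse_path(d: str):
    from matplotlib.path import Path as MplPath

    tokens = d.replace(",", " ").split()
    verts, codes = [], []
    i = 0
    while i < len(tokens):
        cmd = tokens[i]
        if cmd == "M":
            verts.append((float(tokens[i + 1]), float(tokens[i + 2])))
            codes.append(MplPath.MOVETO)
            i += 3
        elif cmd == "L":
            verts.append((float(tokens[i + 1]), float(tokens[i + 2])))
            codes.append(MplPath.LINETO)
            i += 3
        elif cmd == "Q":
            verts.append((float(tokens[i + 1]), float(tokens[i + 2])))
            verts.append((float(tokens[i + 3]), float(tokens[i + 4])))
            codes.extend([MplPath.CURVE3, MplPath.CURVE3])
            i += 5
        elif cmd == "A":  # approximated as a straight segment in raster export
            verts.append((float(tokens[i + 6]), float(tokens[i + 7])))
            codes.append(MplPath.LINETO)
            i += 8
        else:
            i += 1
    return verts, codes


# ---------------------------------------------------------------------------
# style


@dataclass
class StyleSpec:
    """Rendering style shared by all views.

    ``transparency`` is the arc transparency in [0, 1] (default 0.20, i.e.
    arcs are drawn at 80% opacity); ``base_width`` is the stroke width of a
    weight-1 arc in 2D; ``unit_height`` the apex height of a weight-1 arc
    in 3D; ``cumulative`` selects all records up to the current time point
    instead of the single time point; azimuth/elevation set the 3D camera
    in degrees.
    """

    palette: str = "set1"
    transparency: float = 0.20
    base_width: float = 2.0
    unit_height: float = 14.0
    cumulative: bool = False
    azimuth: float = 35.0
    elevation: float = 25.0
    single_color: str = SINGLE_COLOR

    def __post_init__(self) -> None:
        if not 0.0 <= self.transparency <= 1.0:
            raise DataValueError("transparency must lie in [0, 1]")
        if self.base_width <= 0 or self.unit_height <= 0:
            raise DataValueError("base sizes must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 - self.transparency

    def lane_colors(self, ordering: list[str]) -> dict[str, str]:
        # colors follow the post-ordering lane index, stable across views
        cols = palette(self.palette, len(ordering))
        return dict(zip(ordering, cols))


def _arc_color(rec, colors: dict[str, str], style: StyleSpec) -> str:
    return colors[rec.target] if rec.directed else style.single_color


def _select(connections: ConnectionSet, timepoint: int | None, style: StyleSpec):
    if timepoint is None:
        return list(connections.records)
    return connections.at_time(timepoint, cumulative=style.cumulative)


# ---------------------------------------------------------------------------
# arc views


def render_linear(
    connections: ConnectionSet,
    ordering: LaneOrdering | list[str],
    style: StyleSpec | None = None,
    timepoint: int | None = None,
    width: float = 900.0,
    height: float = 420.0,
) -> Scene:
    """Flat 2D arc view: horizontal phenotype lanes in ordering order, time
    on the x axis (ticks labeled 1..n), one quadratic arc per connection
    record with stroke width ``base_width x weight`` and the target
    phenotype's color for directed records."""
    style = style or StyleSpec()
    order = ordering.order if isinstance(ordering, LaneOrdering) else list(ordering)
    missing = set(connections.phenotypes) - set(order)
    if missing:
        raise UnknownEntityError(
            f"ordering is missing phenotypes: {sorted(missing)}"
        )
    colors = style.lane_colors(order)
    n = connections.n_timepoints
    mx, my = 90.0, 40.0
    lane_y = {p: my + i * (height - 2 * my) / max(len(order) - 1, 1) for i, p in enumerate(order)}
    tick_x = {t: mx + t * (width - 2 * mx) / max(n - 1, 1) for t in range(n)}

    scene = Scene(width, height)
    for p in order:
        y = lane_y[p]
        scene.add(
            "line", "lane",
            x1=mx, y1=y, x2=width - mx, y2=y,
            stroke=colors[p], stroke_width=1.5, opacity=0.9,
        )
        scene.add(
            "text", "label", text=p,
            x=mx - 8.0, y=y + 4.0, font_size=11, text_anchor="end",
            fill="#333333",
        )
    for t in range(n):
        scene.add(
            "text", "tick", text=str(t + 1),
            x=tick_x[t], y=height - my + 16.0, font_size=10,
            text_anchor="middle", fill="#555555",
        )
    for rec in _select(connections, timepoint, style):
        x1, y1 = tick_x[rec.t_source], lane_y[rec.source]
        x2, y2 = tick_x[rec.t_target], lane_y[rec.target]
        if x1 == x2:  # lag-0 arc bulges sideways
            cx, cy = x1 + 0.35 * abs(y2 - y1) + 12.0, (y1 + y2) / 2.0
        else:
            cx, cy = (x1 + x2) / 2.0, min(y1, y2) - 0.25 * abs(x2 - x1) - 10.0
        scene.add(
            "path", "arc",
            d=f"M {_f(x1)} {_f(y1)} Q {_f(cx)} {_f(cy)} {_f(x2)} {_f(y2)}",
            fill="none",
            stroke=_arc_color(rec, colors, style),
            stroke_width=style.base_width * rec.weight,
            opacity=style.alpha,
            meta={"weight": rec.weight},
        )
    return scene


def render_circular(
    connections: ConnectionSet,
    timepoint: int,
    style: StyleSpec | None = None,
    size: float = 520.0,
) -> Scene:
    """Circular view for a single time point: phenotypes as equal circle
    segments (spans summing to 360 degrees), chords between segment
    midpoints for every record at that time."""
    style = style or StyleSpec()
    phen = list(connections.phenotypes)
    if not 0 <= timepoint < connections.n_timepoints:
        raise DataValueError(f"time point {timepoint} out of range")
    colors = style.lane_colors(phen)
    P = len(phen)
    cx = cy = size / 2.0
    r = size / 2.0 - 55.0
    span = 360.0 / P
    gap_frac = 0.04  # visual gap inside each span; spans themselves are exact

    scene = Scene(size, size)
    mid_angle: dict[str, float] = {}
    for i, p in enumerate(phen):
        a0 = i * span
        a1 = (i + 1) * span
        mid_angle[p] = (a0 + a1) / 2.0
        b0 = math.radians(a0 + span * gap_frac / 2.0)
        b1 = math.radians(a1 - span * gap_frac / 2.0)
        large = 1 if (b1 - b0) > math.pi else 0
        x0, y0 = cx + r * math.cos(b0), cy + r * math.sin(b0)
        x1p, y1p = cx + r * math.cos(b1), cy + r * math.sin(b1)
        scene.add(
            "path", "segment",
            d=(
                f"M {_f(x0)} {_f(y0)} A {_f(r)} {_f(r)} 0 {large} 1 "
                f"{_f(x1p)} {_f(y1p)}"
            ),
            fill="none", stroke=colors[p], stroke_width=10.0, opacity=1.0,
            meta={"span_deg": span, "phenotype_index": i},
        )
        am = math.radians(mid_angle[p])
        scene.add(
            "text", "label", text=p,
            x=cx + (r + 28.0) * math.cos(am), y=cy + (r + 28.0) * math.sin(am),
            font_size=11, text_anchor="middle", fill="#333333",
        )
    for rec in connections.at_time(timepoint, cumulative=style.cumulative):
        a = math.radians(mid_angle[rec.source])
        b = math.radians(mid_angle[rec.target])
        x1p, y1p = cx + r * math.cos(a), cy + r * math.sin(a)
        x2p, y2p = cx + r * math.cos(b), cy + r * math.sin(b)
        scene.add(
            "path", "arc",
            d=f"M {_f(x1p)} {_f(y1p)} Q {_f(cx)} {_f(cy)} {_f(x2p)} {_f(y2p)}",
            fill="none",
            stroke=_arc_color(rec, colors, style),
            stroke_width=style.base_width * rec.weight,
            opacity=style.alpha,
            meta={"weight": rec.weight},
        )
    return scene


def _project(points: np.ndarray, style: StyleSpec, width: float, height: float) -> np.ndarray:
    """Rotate by azimuth (about the vertical) and elevation, then apply a
    mild perspective divide; returns screen coordinates."""
    az, el = math.radians(style.azimuth), math.radians(style.elevation)
    ra = np.array(
        [
            [math.cos(az), -math.sin(az), 0.0],
            [math.sin(az), math.cos(az), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    re = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(el), -math.sin(el)],
            [0.0, math.sin(el), math.cos(el)],
        ]
    )
    rot = points @ ra.T @ re.T
    depth = 1.0 + 0.0008 * rot[:, 1]
    sx = width * 0.5 + rot[:, 0] / depth
    sy = height * 0.62 - rot[:, 2] / depth + 0.25 * rot[:, 1] / depth
    return np.column_stack([sx, sy])


def render_3d(
    connections: ConnectionSet,
    ordering: LaneOrdering | list[str],
    style: StyleSpec | None = None,
    barseries: BarSeries | None = None,
    timepoint: int | None = None,
    width: float = 900.0,
    height: float = 520.0,
) -> Scene:
    """Static perspective 3D arc view: time along one axis, lanes along the
    depth axis, arcs rising to apex height ``unit_height x weight``;
    optional bar columns per time point scaled to the series maximum."""
    style = style or StyleSpec()
    order = ordering.order if isinstance(ordering, LaneOrdering) else list(ordering)
    missing = set(connections.phenotypes) - set(order)
    if missing:
        raise UnknownEntityError(f"ordering is missing phenotypes: {sorted(missing)}")
    if barseries is not None and len(barseries.values) != connections.n_timepoints:
        raise FormatError(
            f"bar series length {len(barseries.values)} does not match "
            f"{connections.n_timepoints} time points"
        )
    colors = style.lane_colors(order)
    n = connections.n_timepoints
    x_of = {t: (t - (n - 1) / 2.0) * (620.0 / max(n - 1, 1)) for t in range(n)}
    y_of = {p: (i - (len(order) - 1) / 2.0) * (260.0 / max(len(order) - 1, 1)) for i, p in enumerate(order)}

    scene = Scene(width, height)
    for p in order:  # lane base lines on the ground plane
        pts = np.array([[x_of[0], y_of[p], 0.0], [x_of[n - 1], y_of[p], 0.0]])
        s = _project(pts, style, width, height)
        scene.add(
            "line", "lane",
            x1=float(s[0, 0]), y1=float(s[0, 1]),
            x2=float(s[1, 0]), y2=float(s[1, 1]),
            stroke=colors[p], stroke_width=1.5, opacity=0.9,
        )
        scene.add(
            "text", "label", text=p,
            x=float(s[0, 0]) - 8.0, y=float(s[0, 1]) + 4.0,
            font_size=10, text_anchor="end", fill="#333333",
        )
    if barseries is not None:
        vmax = float(np.max(barseries.values)) if np.max(barseries.values) > 0 else 1.0
        y_bar = min(y_of.values()) - 60.0
        for t in range(n):
            h = 80.0 * float(barseries.values[t]) / vmax
            pts = np.array([[x_of[t], y_bar, 0.0], [x_of[t], y_bar, h]])
            s = _project(pts, style, width, height)
            scene.add(
                "line", "bar",
                x1=float(s[0, 0]), y1=float(s[0, 1]),
                x2=float(s[1, 0]), y2=float(s[1, 1]),
                stroke="#888888", stroke_width=6.0, opacity=0.8,
                meta={"value": float(barseries.values[t])},
            )
    for rec in _select(connections, timepoint, style):
        apex = style.unit_height * rec.weight
        p0 = np.array([x_of[rec.t_source], y_of[rec.source], 0.0])
        p2 = np.array([x_of[rec.t_target], y_of[rec.target], 0.0])
        p1 = (p0 + p2) / 2.0 + np.array([0.0, 0.0, 2.0 * apex])
        # tessellate the quadratic Bezier (apex = curve max height = apex)
        ts = np.linspace(0.0, 1.0, 21)[:, None]
        curve = (1 - ts) ** 2 * p0 + 2 * (1 - ts) * ts * p1 + ts**2 * p2
        s = _project(curve, style, width, height)
        pts = " ".join(f"{_f(float(x))},{_f(float(y))}" for x, y in s)
        scene.add(
            "polyline", "arc",
            points=pts, fill="none",
            stroke=_arc_color(rec, colors, style),
            stroke_width=max(style.base_width * 0.75, 1.0),
            opacity=style.alpha,
            meta={"weight": rec.weight, "apex_height": apex},
        )
    return scene


# ---------------------------------------------------------------------------
# heat map and line plot


def render_heatmap(
    dataset: PhenoDataset,
    timepoint: int,
    cluster_result: ClusterResult | None = None,
    style: StyleSpec | None = None,
    cell: float = 18.0,
) -> Scene:
    """Gene x phenotype heat map at one time point, rows/columns permuted
    by the cluster result, diverging color map over the observed range
    (constant data maps everywhere to the midpoint color; missing cells
    are grey)."""
    style = style or StyleSpec()
    if not 0 <= timepoint < dataset.n_timepoints:
        raise DataValueError(f"time point {timepoint} out of range")
    arr = dataset.to_array()[:, :, timepoint]
    rows = cluster_result.row_order if cluster_result else list(range(dataset.n_genes))
    cols = cluster_result.col_order if cluster_result else list(range(dataset.n_phenotypes))
    finite = arr[np.isfinite(arr)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 0.0

    mx, my = 110.0, 70.0
    scene = Scene(mx + cell * len(cols) + 20.0, my + cell * len(rows) + 20.0)
    for ci, j in enumerate(cols):
        scene.add(
            "text", "label", text=dataset.phenotypes[j],
            x=mx + (ci + 0.5) * cell, y=my - 8.0, font_size=9,
            text_anchor="middle", fill="#333333",
        )
    for ri, i in enumerate(rows):
        scene.add(
            "text", "label", text=dataset.genes[i],
            x=mx - 6.0, y=my + (ri + 0.7) * cell, font_size=9,
            text_anchor="end", fill="#333333",
        )
        for ci, j in enumerate(cols):
            v = arr[i, j]
            if np.isnan(v):
                fill = "#cccccc"
            elif vmax == vmin:
                fill = diverging_color(0.5)
            else:
                fill = diverging_color((v - vmin) / (vmax - vmin))
            scene.add(
                "rect", "cell",
                x=mx + ci * cell, y=my + ri * cell, width=cell, height=cell,
                fill=fill, opacity=1.0,
            )
    return scene


def render_lineplot(
    dataset: PhenoDataset,
    phenotype: str,
    style: StyleSpec | None = None,
    width: float = 700.0,
    height: float = 380.0,
) -> Scene:
    """Timeline of every gene's score for one phenotype; a missing value
    breaks the polyline into separate segments."""
    style = style or StyleSpec()
    if phenotype not in dataset.phenotypes:
        raise UnknownEntityError(f"unknown phenotype {phenotype!r}")
    j = dataset.phenotypes.index(phenotype)
    arr = dataset.to_array()[:, j, :]
    finite = arr[np.isfinite(arr)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    n = dataset.n_timepoints
    mx, my = 70.0, 40.0
    x_of = lambda t: mx + t * (width - 2 * mx) / max(n - 1, 1)  # noqa: E731
    y_of = lambda v: height - my - (v - vmin) / (vmax - vmin) * (height - 2 * my)  # noqa: E731

    scene = Scene(width, height)
    scene.add(
        "line", "axis", x1=mx, y1=height - my, x2=width - mx, y2=height - my,
        stroke="#333333", stroke_width=1.0, opacity=1.0,
    )
    scene.add(
        "line", "axis", x1=mx, y1=my, x2=mx, y2=height - my,
        stroke="#333333", stroke_width=1.0, opacity=1.0,
    )
    for t in range(n):
        scene.add(
            "text", "tick", text=str(t + 1),
            x=x_of(t), y=height - my + 16.0, font_size=9,
            text_anchor="middle", fill="#555555",
        )
    cols = palette(style.palette, min(dataset.n_genes, len(PALETTES.get(style.palette, [SINGLE_COLOR] * 99)))) if style.palette != "single" else []
    for gi, gene in enumerate(dataset.genes):
        color = cols[gi % len(cols)] if cols else SINGLE_COLOR
        run: list[tuple[float, float]] = []
        segments: list[list[tuple[float, float]]] = []
        for t in range(n):
            v = arr[gi, t]
            if np.isnan(v):
                if len(run) >= 2:
                    segments.append(run)
                run = []
            else:
                run.append((x_of(t), y_of(float(v))))
        if len(run) >= 2:
            segments.append(run)
        for seg in segments:
            scene.add(
                "polyline", "series",
                points=" ".join(f"{_f(x)},{_f(y)}" for x, y in seg),
                fill="none", stroke=color, stroke_width=1.5,
                opacity=0.9, meta={"gene": gene},
            )
    return scene
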