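"""Radial tree layout and figure export.

The root sits at the centre; each node owns an angular span split among
its children in proportion to their leaf counts (or cell counts, on
request), and radius grows outward either in uniform unit steps or by
the parent's split distance when branch scaling is enabled. Figures are
written as SVG 1.1 built element-by-element; PNG export rasterizes the
package's own SVG dialect (lines, wedges, circles, rects) with Pillow.

Everything about one figure — scales, colors, overlays, the prune
history that produced the displayed tree, export format — lives in a
:class:`RenderConfig` that round-trips losslessly through JSON, so a
figure refined once can be replayed as a template for batch processing.
"""

from __future__ import annotations

import io
import json
import math
import os
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .cluster_tree import ClusterNode, ClusterTree
from .overlay import NodeOverlay, OverlayKind
from .prune import PruneHistory
from .tree_io import LabelMap

__all__ = [
    "LayoutNode", "RenderConfig", "ConfigValidationError", "SvgDocument",
    "radial_layout", "compute_branch_widths", "render_svg", "render_png",
    "config_to_json", "config_from_json", "save_config", "load_config",
]

CONFIG_SCHEMA_VERSION = "celltree-config/1"

#: minimum edge length under distance scaling, as a fraction of the
#: maximum cumulative radius, so zero-distance splits stay visible
EPS_MIN_FRACTION = 0.01


class ConfigValidationError(ValueError):
    pass


@dataclass
class LayoutNode:
    node_id: int
    angle: float
    radius: float
    angular_span: tuple[float, float]
    parent_id: int | None


def radial_layout(t: ClusterTree, scale_by_distance: bool = False,
                  weight_by: str = "leaves") -> dict[int, LayoutNode]:
    """Place every node on the radial plane.

    The root takes the full circle [0, 2pi); children split their
    parent's span proportionally to leaf counts (``weight_by="cells"``
    weights by cell counts instead). A node sits at its span midpoint.
    Without distance scaling each generation steps one radius unit
    outward; with it, the step equals the parent's split distance,
    floored at 1% of the deepest cumulative distance.
    """
    if weight_by not in ("leaves", "cells"):
        raise ValueError(f"unknown weight_by {weight_by!r}")

    def weight(n: ClusterNode) -> int:
        if weight_by == "cells":
            return n.n_cells()
        return sum(1 for _ in _iter_leaves(n))

    # first pass: raw radii, to learn the scale for the epsilon floor
    def raw_radius(n: ClusterNode, r: float, acc: dict[int, float]) -> None:
        acc[n.node_id] = r
        for c in n.children:
            step = max(n.distance, 0.0) if scale_by_distance else 1.0
            raw_radius(c, r + step, acc)

    raw: dict[int, float] = {}
    raw_radius(t.root, 0.0, raw)
    max_raw = max(raw.values())
    eps = EPS_MIN_FRACTION * max_raw if max_raw > 0 else EPS_MIN_FRACTION

    layout: dict[int, LayoutNode] = {}

    def place(n: ClusterNode, span: tuple[float, float], r: float,
              parent_id: int | None) -> None:
        layout[n.node_id] = LayoutNode(
            node_id=n.node_id,
            angle=(span[0] + span[1]) / 2.0 % (2 * math.pi),
            radius=r,
            angular_span=span,
            parent_id=parent_id,
        )
        if n.is_leaf:
            return
        total = sum(weight(c) for c in n.children)
        start = span[0]
        step = max(n.distance, eps) if scale_by_distance else 1.0
        for c in n.children:
            frac = weight(c) / total
            end = start + (span[1] - span[0]) * frac
            place(c, (start, end), r + step, n.node_id)
            start = end

    place(t.root, (0.0, 2 * math.pi), 0.0, None)
    return layout


def _iter_leaves(node: ClusterNode):
    if node.is_leaf:
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


def compute_branch_widths(t: ClusterTree, width_range: tuple[float, float]) -> dict[int, float]:
    """Per-node stroke width, log-scaled in the node's cell count.

    width = min + (max - min) * log1p(n_node) / log1p(n_root); the root
    always gets the maximum.
    """
    lo, hi = width_range
    if lo > hi:
        raise ValueError("width range min exceeds max")
    n_root = t.root.n_cells()
    denom = math.log1p(n_root)
    widths = {}
    for node in t.nodes():
        frac = math.log1p(node.n_cells()) / denom if denom > 0 else 1.0
        widths[node.node_id] = lo + (hi - lo) * frac
    return widths


# -- configuration ------------------------------------------------------

_CONFIG_FIELDS: dict[str, type | tuple[type, ...]] = {
    "scale_by_distance": bool,
    "global_scale": (int, float),
    "branch_width_range": (list, tuple),
    "color_map": dict,
    "feature_overlays": list,
    "prune_history": list,
    "export": str,
    "width_px": int,
    "height_px": int,
    "show_legend": bool,
    "seed": int,
    "overlay_low_color": str,
    "overlay_high_color": str,
}


@dataclass
class RenderConfig:
    """Complete, serializable description of one figure."""

    scale_by_distance: bool = False
    global_scale: float = 1.0
    branch_width_range: tuple[float, float] = (1.0, 10.0)
    color_map: dict[str, str] = field(default_factory=dict)
    feature_overlays: list[dict] = field(default_factory=list)
    prune_history: PruneHistory = field(default_factory=PruneHistory)
    export: str = "svg"
    width_px: int = 800
    height_px: int = 800
    show_legend: bool = True
    seed: int = 0
    overlay_low_color: str = "#E5E5E5"
    overlay_high_color: str = "#D62728"

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ConfigValidationError("global_scale must be > 0")
        if self.export not in ("svg", "png"):
            raise ConfigValidationError(f"export must be svg or png, got {self.export!r}")
        if len(self.feature_overlays) > 2:
            raise ConfigValidationError("at most 2 feature overlays supported")
        lo, hi = self.branch_width_range
        if lo > hi:
            raise ConfigValidationError("branch_width_range min exceeds max")

    def to_obj(self) -> dict:
        return {
            "version": CONFIG_SCHEMA_VERSION,
            "scale_by_distance": self.scale_by_distance,
            "global_scale": self.global_scale,
            "branch_width_range": list(self.branch_width_range),
            "color_map": dict(self.color_map),
            "feature_overlays": [dict(o) for o in self.feature_overlays],
            "prune_history": self.prune_history.to_obj(),
            "export": self.export,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "show_legend": self.show_legend,
            "seed": self.seed,
            "overlay_low_color": self.overlay_low_color,
            "overlay_high_color": self.overlay_high_color,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "RenderConfig":
        if not isinstance(obj, dict):
            raise ConfigValidationError("config must be a JSON object")
        version = obj.get("version")
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigValidationError(
                f"version: expected {CONFIG_SCHEMA_VERSION!r}, got {version!r}"
            )
        unknown = set(obj) - set(_CONFIG_FIELDS) - {"version"}
        if unknown:
            raise ConfigValidationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for key, types in _CONFIG_FIELDS.items():
            if key not in obj:
                continue
            val = obj[key]
            bad = not isinstance(val, types)
            if types is not bool and isinstance(val, bool):
                bad = True  # bool is an int subclass; don't let it pass for numbers
            if bad:
                raise ConfigValidationError(
                    f"{key}: expected {types}, got {type(val).__name__}"
                )
            kwargs[key] = val
        if "branch_width_range" in kwargs:
            kwargs["branch_width_range"] = tuple(kwargs["branch_width_range"])
        if "prune_history" in kwargs:
            kwargs["prune_history"] = PruneHistory.from_obj(kwargs["prune_history"])
        return cls(**kwargs)


def config_to_json(config: RenderConfig) -> str:
    return json.dumps(config.to_obj(), indent=1, sort_keys=False) + "\n"


def config_from_json(text: str) -> RenderConfig:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise ConfigValidationError(f"malformed config JSON: {e}") from e
    return RenderConfig.from_obj(obj)


def save_config(config: RenderConfig, path: str | os.PathLike) -> None:
    Path(path).write_text(config_to_json(config), encoding="utf-8")


def load_config(path: str | os.PathLike) -> RenderConfig:
    return config_from_json(Path(path).read_text(encoding="utf-8"))


# -- SVG generation -----------------------------------------------------


@dataclass
class SvgDocument:
    """An SVG figure plus its pixel dimensions."""

    xml: str
    width_px: int
    height_px: int

    def __str__(self) -> str:
        return self.xml

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(self.xml, encoding="utf-8")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)


def _rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#%02X%02X%02X" % rgb


def _lerp_color(lo: str, hi: str, frac: float) -> str:
    a, b = _hex_to_rgb(lo), _hex_to_rgb(hi)
    frac = min(1.0, max(0.0, frac))
    return _rgb_to_hex(tuple(round(x + (y - x) * frac) for x, y in zip(a, b)))


def overlay_color_scale(overlay: NodeOverlay, low_color: str, high_color: str) -> dict[int, str]:
    """Map node means onto the two-color linear scale over [min, max].

    Monotone by construction: a higher node mean never gets a lower
    scale position.
    """
    vals = {k: float(v) for k, v in overlay.values.items()}
    vmin, vmax = min(vals.values()), max(vals.values())
    span = vmax - vmin
    return {
        k: _lerp_color(low_color, high_color, (v - vmin) / span if span > 0 else 0.5)
        for k, v in vals.items()
    }


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _polar(cx: float, cy: float, r: float, angle: float) -> tuple[float, float]:
    return cx + r * math.cos(angle), cy - r * math.sin(angle)


def _add_wedge(parent: ET.Element, cx: float, cy: float, r: float,
               a0: float, a1: float, fill: str) -> None:
    """A filled pie wedge from angle a0 to a1 (radians, ccw)."""
    if a1 - a0 >= 2 * math.pi - 1e-9:
        ET.SubElement(parent, "circle", cx=_fmt(cx), cy=_fmt(cy), r=_fmt(r),
                      fill=fill)
        return
    x0, y0 = _polar(cx, cy, r, a0)
    x1, y1 = _polar(cx, cy, r, a1)
    large = "1" if (a1 - a0) > math.pi else "0"
    d = (f"M {_fmt(cx)} {_fmt(cy)} L {_fmt(x0)} {_fmt(y0)} "
         f"A {_fmt(r)} {_fmt(r)} 0 {large} 0 {_fmt(x1)} {_fmt(y1)} Z")
    ET.SubElement(parent, "path", d=d, fill=fill, attrib={
        "data-cx": _fmt(cx), "data-cy": _fmt(cy), "data-r": _fmt(r),
        "data-a0": _fmt(a0), "data-a1": _fmt(a1),
    })


def render_svg(t: ClusterTree, layout: Mapping[int, LayoutNode],
               config: RenderConfig,
               overlays: NodeOverlay | None = None,
               labels: LabelMap | None = None) -> SvgDocument:
    """Draw the tree: one link path per parent-child edge, one glyph per node.

    Node glyphs are pie charts of label composition when ``labels`` is
    given, solid circles colored by the overlay scale when ``overlays``
    is a mean-feature overlay, and neutral circles otherwise. Every glyph
    group carries its node id in a ``data-node-id`` attribute.
    """
    missing = [n.node_id for n in t.nodes() if n.node_id not in layout]
    if missing:
        raise ValueError(f"layout missing node(s) {missing[:3]}")
    if overlays is not None and overlays.kind is OverlayKind.MEAN_FEATURE:
        missing_ov = [n.node_id for n in t.nodes() if n.node_id not in overlays.values]
        if missing_ov:
            raise ValueError(f"overlay missing node(s) {missing_ov[:3]}")

    w, h = config.width_px, config.height_px
    cx, cy = w / 2.0, h / 2.0
    max_r = max(ln.radius for ln in layout.values())
    plot_r = 0.42 * min(w, h) * config.global_scale
    scale = plot_r / max_r if max_r > 0 else 0.0

    def xy(ln: LayoutNode) -> tuple[float, float]:
        return _polar(cx, cy, ln.radius * scale, ln.angle)

    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     width=str(w), height=str(h),
                     viewBox=f"0 0 {w} {h}", version="1.1")
    ET.SubElement(svg, "rect", x="0", y="0", width=str(w), height=str(h),
                  fill="#FFFFFF")

    widths = compute_branch_widths(t, config.branch_width_range)
    node_comp = None
    if labels is not None:
        from .overlay import node_label_composition
        node_comp = node_label_composition(t, labels)
    node_fill: dict[int, str] = {}
    if overlays is not None and overlays.kind is OverlayKind.MEAN_FEATURE:
        node_fill = overlay_color_scale(
            overlays, config.overlay_low_color, config.overlay_high_color)

    links = ET.SubElement(svg, "g", attrib={"class": "links"})
    for node in t.nodes():
        for child in node.children:
            x0, y0 = xy(layout[node.node_id])
            x1, y1 = xy(layout[child.node_id])
            ET.SubElement(links, "path", attrib={
                "class": "link",
                "d": f"M {_fmt(x0)} {_fmt(y0)} L {_fmt(x1)} {_fmt(y1)}",
                "stroke": "#999999",
                "stroke-width": _fmt(widths[child.node_id]),
                "fill": "none",
            })

    glyph_r = max(3.0, 0.035 * plot_r)
    nodes_g = ET.SubElement(svg, "g", attrib={"class": "nodes"})
    for node in t.nodes():
        x, y = xy(layout[node.node_id])
        g = ET.SubElement(nodes_g, "g", attrib={
            "class": "node", "data-node-id": str(node.node_id)})
        if node_comp is not None:
            counts = node_comp[node.node_id]
            total = sum(counts.values())
            a = 0.0
            for lab in sorted(counts):
                frac = counts[lab] / total
                _add_wedge(g, x, y, glyph_r, a, a + frac * 2 * math.pi,
                           config.color_map.get(lab)
                           or (labels.color_of.get(lab, "#888888")))
                a += frac * 2 * math.pi
        else:
            fill = node_fill.get(node.node_id, "#888888")
            ET.SubElement(g, "circle", cx=_fmt(x), cy=_fmt(y),
                          r=_fmt(glyph_r), fill=fill)

    if config.show_legend and labels is not None:
        legend = ET.SubElement(svg, "g", attrib={"class": "legend"})
        y0 = 20.0
        for i, lab in enumerate(sorted(labels.color_of)):
            col = config.color_map.get(lab) or labels.color_of[lab]
            ET.SubElement(legend, "rect", x="10", y=_fmt(y0 + 18 * i),
                          width="12", height="12", fill=col)
            txt = ET.SubElement(legend, "text", x="26", y=_fmt(y0 + 18 * i + 10),
                                attrib={"font-size": "12",
                                        "font-family": "sans-serif"})
            txt.text = lab

    xml = ET.tostring(svg, encoding="unicode")
    return SvgDocument('<?xml version="1.0" encoding="UTF-8"?>\n' + xml + "\n", w, h)


# -- PNG rasterization --------------------------------------------------

_LINE_RE = re.compile(
    r"M\s+(-?[\d.]+)\s+(-?[\d.]+)\s+L\s+(-?[\d.]+)\s+(-?[\d.]+)\s*$")


def render_png(svg_doc: SvgDocument | str, width_px: int | None = None) -> bytes:
    """Rasterize a figure produced by :func:`render_svg` to PNG bytes.

    Understands this package's SVG dialect (rects, circles, straight-line
    link paths and wedge paths carrying their polar parameters as data-
    attributes; legend text is drawn with Pillow's default font). Aspect
    ratio is preserved when ``width_px`` differs from the document's.
    """
    try:
        from PIL import Image, ImageDraw
    except ImportError as e:  # pragma: no cover - Pillow is a hard dep
        raise RuntimeError(
            "PNG export needs Pillow; install it or export SVG instead"
        ) from e

    xml = svg_doc.xml if isinstance(svg_doc, SvgDocument) else str(svg_doc)
    root = ET.fromstring(xml)
    doc_w = float(root.get("width"))
    doc_h = float(root.get("height"))
    out_w = int(width_px) if width_px else int(doc_w)
    s = out_w / doc_w
    out_h = max(1, round(doc_h * s))

    # supersample x2 for smoother edges, deterministic integer math
    ss = 2
    img = Image.new("RGB", (out_w * ss, out_h * ss), "#FFFFFF")
    draw = ImageDraw.Draw(img)
    k = s * ss

    def walk(el: ET.Element) -> None:
        tag = el.tag.split("}")[-1]
        if tag == "rect":
            x, y = float(el.get("x", 0)) * k, float(el.get("y", 0)) * k
            w_, h_ = float(el.get("width")) * k, float(el.get("height")) * k
            draw.rectangle([x, y, x + w_, y + h_], fill=el.get("fill", "#000000"))
        elif tag == "circle":
            cx, cy = float(el.get("cx")) * k, float(el.get("cy")) * k
            r = float(el.get("r")) * k
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=el.get("fill"))
        elif tag == "path":
            d = el.get("d", "")
            if el.get("data-r") is not None:
                cx = float(el.get("data-cx")) * k
                cy = float(el.get("data-cy")) * k
                r = float(el.get("data-r")) * k
                a0 = float(el.get("data-a0"))
                a1 = float(el.get("data-a1"))
                # SVG y grows downward: ccw math angles become cw screen arcs
                draw.pieslice([cx - r, cy - r, cx + r, cy + r],
                              start=-math.degrees(a1), end=-math.degrees(a0),
                              fill=el.get("fill"))
            else:
                mline = _LINE_RE.match(d)
                if mline:
                    x0, y0, x1, y1 = (float(v) * k for v in mline.groups())
                    lw = max(1, round(float(el.get("stroke-width", 1)) * k))
                    draw.line([x0, y0, x1, y1], fill=el.get("stroke", "#000000"),
                              width=lw)
        elif tag == "text":
            x, y = float(el.get("x")) * k, float(el.get("y")) * k
            draw.text((x, y - 10 * k / 2), el.text or "", fill="#000000")
        for child in el:
            walk(child)

    walk(root)
    img = img.resize((out_w, out_h), Image.BILINEAR)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
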