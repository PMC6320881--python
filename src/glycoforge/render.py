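"""SNFG-compliant SVG rendering.

Monosaccharides are drawn as SNFG symbols on the layout grid; glycosidic
edges are straight lines whose stroke pattern encodes the donor's
anomericity (solid = beta, dashed = alpha, dotted = undetermined) and whose
angle encodes the linkage position (via the layout).  Base + substituent
patterns with a dedicated SNFG symbol (GlcN + n-acetyl -> GlcNAc blue
square, Neu + n-acetyl@5 -> Neu5Ac purple diamond, ...) are fused into a
single symbol; any other substituent becomes a small text decoration such
as "6S" next to its parent.

Output is deterministic: identical (glycan, layout, options) give
byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

from .layout import layout_glycan
from .model import Glycan, Monosaccharide, RepeatUnit
from .vocab import SNFG_COLORS, UNKNOWN, Anomer

#: (base type, ((substituent name, position), ...)) -> fused symbol
FUSION_TABLE = {
    ("GlcN", ("n-acetyl", 2)): ("square", "blue", "GlcNAc"),
    ("GalN", ("n-acetyl", 2)): ("square", "yellow", "GalNAc"),
    ("ManN", ("n-acetyl", 2)): ("square", "green", "ManNAc"),
    ("Neu", ("n-acetyl", 5)): ("diamond", "purple", "Neu5Ac"),
    ("Neu", ("n-glycolyl", 5)): ("diamond", "lightblue", "Neu5Gc"),
}

DASH_PATTERNS = {
    Anomer.ALPHA: "6,4",
    Anomer.BETA: None,
    Anomer.OPEN: None,
    Anomer.UNDETERMINED: "2,3",
}

STYLE_NAMES = {
    Anomer.ALPHA: "dashed",
    Anomer.BETA: "solid",
    Anomer.OPEN: "solid",
    Anomer.UNDETERMINED: "dotted",
}


def edge_style(anomericity) -> str:
    """Stroke style token for an anomericity (total over the vocabulary)."""
    return STYLE_NAMES[Anomer(anomericity)]


@dataclass(frozen=True)
class SymbolSpec:
    shape: str
    color: str
    color_hex: str = None
    label: str = None
    decorations: tuple = ()           # ((position-or-UNKNOWN, label), ...)

    def __post_init__(self):
        if self.color_hex is None:
            object.__setattr__(self, "color_hex", SNFG_COLORS[self.color])


@dataclass
class RenderOptions:
    cell_px: int = 60
    symbol_px: int = 36
    show_linkage_labels: bool = True
    dash_patterns: dict = field(default_factory=lambda: dict(DASH_PATTERNS))
    margin_cells: int = 1

    def __post_init__(self):
        if self.symbol_px >= self.cell_px:
            raise ValueError("symbol_px must be smaller than cell_px")


def symbol_for(residue, substituents=()) -> SymbolSpec:
    """SNFG symbol for a residue plus its attached substituents.

    ``substituents`` is an iterable of (SubstituentType-or-name, position)
    pairs.  Fusable patterns collapse to the composite symbol; anything left
    over is returned as a text decoration.
    """
    mtype = residue.mtype if isinstance(residue, Monosaccharide) else residue
    subs = [(s.name if hasattr(s, "name") else s, p) for s, p in substituents]
    shape, color, label = mtype.snfg_shape, mtype.snfg_color, None
    for (s, p) in list(subs):
        fused = FUSION_TABLE.get((mtype.name, (s, p)))
        if fused:
            shape, color, label = fused
            subs.remove((s, p))
            break
    from .vocab import SUBSTITUENTS
    decorations = tuple(
        (p, f"{'' if p is UNKNOWN else p}{SUBSTITUENTS[s].label}")
        for s, p in sorted(subs, key=lambda sp: (sp[1] is UNKNOWN,
                                                 0 if sp[1] is UNKNOWN else sp[1],
                                                 sp[0])))
    return SymbolSpec(shape=shape, color=color, label=label,
                      decorations=decorations)


def _fmt(x: float) -> str:
    return f"{x:.1f}".rstrip("0").rstrip(".")


def _polygon(parent, points, fill, stroke="#000000", extra=None):
    attrs = {"points": " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points),
             "fill": fill, "stroke": stroke, "stroke-width": "1.5"}
    if extra:
        attrs.update(extra)
    return ET.SubElement(parent, "polygon", attrs)


def _regular_points(cx, cy, r, n, phase):
    return [(cx + r * math.cos(phase + 2 * math.pi * k / n),
             cy + r * math.sin(phase + 2 * math.pi * k / n)) for k in range(n)]


def _star_points(cx, cy, r, n=5):
    pts = []
    for k in range(2 * n):
        rad = r if k % 2 == 0 else r * 0.42
        ang = -math.pi / 2 + math.pi * k / n
        pts.append((cx + rad * math.cos(ang), cy + rad * math.sin(ang)))
    return pts


def _draw_symbol(group, spec: SymbolSpec, cx, cy, size):
    h = size / 2.0
    fill = spec.color_hex
    stroke = {"stroke": "#000000", "stroke-width": "1.5"}
    shape = spec.shape
    if shape == "circle":
        ET.SubElement(group, "circle", {"cx": _fmt(cx), "cy": _fmt(cy),
                                        "r": _fmt(h), "fill": fill, **stroke})
    elif shape in ("square", "crossed-square"):
        attrs = {"x": _fmt(cx - h), "y": _fmt(cy - h), "width": _fmt(size),
                 "height": _fmt(size), **stroke}
        if shape == "square":
            ET.SubElement(group, "rect", {**attrs, "fill": fill})
        else:
            ET.SubElement(group, "rect", {**attrs, "fill": "#FFFFFF"})
            _polygon(group, [(cx - h, cy - h), (cx + h, cy - h), (cx - h, cy + h)],
                     fill)
            ET.SubElement(group, "rect", {**attrs, "fill": "none"})
    elif shape in ("diamond", "divided-diamond"):
        pts = [(cx, cy - h), (cx + h, cy), (cx, cy + h), (cx - h, cy)]
        if shape == "diamond":
            _polygon(group, pts, fill)
        else:
            _polygon(group, pts, "#FFFFFF")
            _polygon(group, [pts[3], pts[0], pts[1]], fill)
            _polygon(group, pts, "none")
    elif shape in ("triangle", "divided-triangle"):
        pts = [(cx, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
        if shape == "triangle":
            _polygon(group, pts, fill)
        else:
            _polygon(group, pts, "#FFFFFF")
            _polygon(group, [pts[0], pts[1], (cx, cy + h)], fill)
            _polygon(group, pts, "none")
    elif shape == "star":
        _polygon(group, _star_points(cx, cy, h * 1.15), fill)
    elif shape == "hexagon":
        pts = [(cx - h, cy), (cx - h * 0.5, cy - h * 0.62),
               (cx + h * 0.5, cy - h * 0.62), (cx + h, cy),
               (cx + h * 0.5, cy + h * 0.62), (cx - h * 0.5, cy + h * 0.62)]
        _polygon(group, pts, fill)
    elif shape == "pentagon":
        _polygon(group, _regular_points(cx, cy, h, 5, -math.pi / 2), fill)
    elif shape in ("rectangle", "flat-rectangle"):
        ET.SubElement(group, "rect", {
            "x": _fmt(cx - h), "y": _fmt(cy - h * 0.55), "width": _fmt(size),
            "height": _fmt(size * 0.55), "fill": fill, **stroke})
    else:  # pragma: no cover - vocabulary restricts shapes
        raise ValueError(f"unknown SNFG shape {shape!r}")


def _linkage_label(link) -> str:
    donor = "?" if link.donor_position is UNKNOWN else str(link.donor_position)
    stated = sorted(p for p in link.acceptor_positions if p is not UNKNOWN)
    acc = "/".join(str(p) for p in stated) if stated else "?"
    return f"{donor}→{acc}"


def render_svg(g: Glycan, layout=None, options=None) -> str:
    """Render a glycan (and optional precomputed layout) to SVG 1.1 text."""
    options = options or RenderOptions()
    if g.root_id is None:
        svg = ET.Element("svg", {
            "xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
            "width": "40", "height": "40", "viewBox": "0 0 40 40"})
        return ET.tostring(svg, encoding="unicode")
    if layout is None:
        layout = layout_glycan(g)

    cols = [c for c, _ in layout.occupied]
    rows = [r for _, r in layout.occupied]
    m = options.margin_cells
    cell = options.cell_px
    width = (max(cols) - min(cols) + 1 + 2 * m) * cell
    height = (max(rows) - min(rows) + 1 + 2 * m) * cell

    def px(cellpos):
        c, r = cellpos
        x = (c - min(cols) + m + 0.5) * cell
        # SVG y grows downward; row +1 (the 6-arm) must appear above
        y = (max(rows) - r + m + 0.5) * cell
        return x, y

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
        "width": _fmt(width), "height": _fmt(height),
        "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}"})

    edges = ET.SubElement(svg, "g", {"class": "edges"})
    symbols = ET.SubElement(svg, "g", {"class": "residues"})

    for nid in sorted(layout.cells):
        node = g.nodes[nid]
        parent = g.parent_of(nid)
        if parent is not None and parent in layout.cells:
            link = g.linkage_of(nid)
            if isinstance(node, RepeatUnit):
                root = node.internal_glycan.nodes[node.internal_glycan.root_id]
                anomer = (root.anomericity if isinstance(root, Monosaccharide)
                          else Anomer.UNDETERMINED)
            else:
                anomer = node.anomericity
            (x1, y1), (x2, y2) = px(layout.cells[parent]), px(layout.cells[nid])
            attrs = {"x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2),
                     "y2": _fmt(y2), "stroke": "#000000", "stroke-width": "2",
                     "class": f"edge anomer-{anomer.value}",
                     "data-parent": str(parent), "data-child": str(nid)}
            dash = options.dash_patterns[anomer]
            if dash:
                attrs["stroke-dasharray"] = dash
            ET.SubElement(edges, "line", attrs)
            if options.show_linkage_labels:
                ET.SubElement(edges, "text", {
                    "x": _fmt((x1 + x2) / 2), "y": _fmt((y1 + y2) / 2 - 4),
                    "font-size": "10", "text-anchor": "middle",
                    "class": "linkage-label"}).text = _linkage_label(link)

    for nid in sorted(layout.cells):
        node = g.nodes[nid]
        cx, cy = px(layout.cells[nid])
        group = ET.SubElement(symbols, "g", {
            "class": "residue", "data-node": str(nid)})
        if isinstance(node, RepeatUnit):
            _render_repeat(group, g, node, cx, cy, options)
            continue
        subs = [(g.nodes[c].stype, g.linkage_of(c))
                for c in g.substituent_children(nid)]
        spec = symbol_for(node, subs)
        _draw_symbol(group, spec, cx, cy, options.symbol_px)
        for i, (_, text) in enumerate(spec.decorations):
            ET.SubElement(group, "text", {
                "x": _fmt(cx + options.symbol_px * 0.7),
                "y": _fmt(cy - options.symbol_px * 0.55 + 11 * i),
                "font-size": "10", "class": "decoration"}).text = text

    return ET.tostring(svg, encoding="unicode")


def _render_repeat(group, g, unit: RepeatUnit, cx, cy, options):
    """A repeat unit drawn as its unit-root symbol between brackets."""
    ig = unit.internal_glycan
    root = ig.nodes[ig.root_id]
    if isinstance(root, Monosaccharide):
        subs = [(ig.nodes[c].stype, ig.linkage_of(c))
                for c in ig.substituent_children(ig.root_id)]
        _draw_symbol(group, symbol_for(root, subs), cx, cy, options.symbol_px)
    h = options.symbol_px * 0.8
    w = options.symbol_px * 0.25
    for sign, x in ((1, cx - options.symbol_px), (-1, cx + options.symbol_px)):
        d = (f"M {_fmt(x + sign * w)} {_fmt(cy - h)} L {_fmt(x)} {_fmt(cy - h)} "
             f"L {_fmt(x)} {_fmt(cy + h)} L {_fmt(x + sign * w)} {_fmt(cy + h)}")
        ET.SubElement(group, "path", {"d": d, "stroke": "#000000",
                                      "stroke-width": "2", "fill": "none",
                                      "class": "repeat-bracket"})
    lo = "?" if unit.min_count is UNKNOWN else str(unit.min_count)
    hi = "?" if unit.max_count is UNKNOWN else str(unit.max_count)
    label = lo if lo == hi else f"{lo}–{hi}"
    ET.SubElement(group, "text", {
        "x": _fmt(cx + options.symbol_px * 1.1),
        "y": _fmt(cy + h + 10), "font-size": "11",
        "class": "repeat-count"}).text = label
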