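"""SVG emission: painted frames, animations, legend histograms, omics popups.

Animation is emitted as one SVG per frame plus a JSON index (frame order,
labels, file names) rather than scripted/SMIL animation: frame files with
identical geometry and differing only in presentation attributes are directly
assertable, and any viewer or post-processor can step them.

Element ids equal network ids sanitized to SVG NCName rules (non-alphanumerics
become ``_``); each element carries a ``<title>`` child naming the entity, the
hover-tooltip equivalent.  When one reaction is drawn in several pathways, the
later occurrences get an ``__n`` suffix to keep document ids unique; all
occurrences are painted alike via a shared ``data-ref`` attribute.
"""

from __future__ import annotations

import json
import logging
import math
import os
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .layout import Diagram, Glyph
from .mapping import (
    ChannelState,
    HistogramSummary,
    resolve_targets,
    value_to_color,
    value_to_thickness,
)
from .network import MetabolicNetwork
from .omics import MultiOmicsExperiment

log = logging.getLogger(__name__)

SVG_NS = "http://www.w3.org/2000/svg"

NEUTRAL_EDGE = {"stroke": "#999999", "stroke-width": "1"}
NEUTRAL_NODE_FILL = "#f5f5f5"
NODE_OUTLINE = "#444444"
SHADE_FILL = "#d0d0d0"


class RenderConfigError(ValueError):
    """A dataset targets a channel with no configured state, or similar."""


class NoDataError(ValueError):
    """Popup requested for an entity untouched by every dataset."""


def sanitize_id(raw: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_.-]", "_", raw)
    return s if s and not s[0].isdigit() else f"_{s}"


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


# -- frame construction ----------------------------------------------------

_STYLE_KEY = {
    "edge_color": "stroke",
    "edge_thickness": "stroke-width",
    "node_color": "fill",
    "node_thickness": "stroke-width",
}


@dataclass
class FrameSet:
    """Per-frame style maps (target id -> svg presentation attributes)."""

    frames: list[dict[str, dict[str, str]]]
    frame_labels: list[str]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def build_frames(
    diagram: Diagram,
    experiment: MultiOmicsExperiment,
    channel_states: dict[str, ChannelState],
    network: MetabolicNetwork,
    aggregation: str = "max_magnitude",
) -> FrameSet:
    """Resolve every dataset onto the diagram and compute per-frame styles.

    Each dataset paints one style attribute of its resolved targets; entities
    measured by no dataset keep the neutral style.  Datasets narrower than the
    experiment's frame count hold their last value, so a single-time-point
    metabolomics layer stays constant while others animate.
    """
    n = experiment.n_frames
    frames: list[dict[str, dict[str, str]]] = [dict() for _ in range(n)]
    known_ids = diagram.reaction_edge_ids() | diagram.compound_node_ids()
    for ds in experiment.datasets:
        ch = ds.spec.target_channel
        state = channel_states.get(ch)
        if state is None:
            raise RenderConfigError(f"dataset {ds.spec.dataset_id!r} targets "
                                    f"{ch!r} but no channel state is configured")
        if state.channel != ch:
            raise RenderConfigError(f"channel state for {ch!r} is labeled {state.channel!r}")
        resolved = resolve_targets(ds, network, aggregation=aggregation, n_frames=n)
        key = _STYLE_KEY[ch]
        for series in resolved:
            if series.target_id not in known_ids:
                log.warning("resolved target %r has no glyph; skipped", series.target_id)
                continue
            for f in range(n):
                v = series.values[f]
                if state.is_color:
                    styled = value_to_color(v, state)
                else:
                    styled = _fmt_width(value_to_thickness(v, state))
                frames[f].setdefault(series.target_id, {})[key] = styled
    return FrameSet(frames=frames, frame_labels=experiment.frame_labels())


def _fmt_width(w: float) -> str:
    return f"{w:.3f}".rstrip("0").rstrip(".") or "0"


# -- SVG document construction --------------------------------------------


def _el(parent, tag, **attrs):
    e = ET.SubElement(parent, tag)
    for k, v in attrs.items():
        e.set(k.replace("_", "-"), str(v))
    return e


def _title(parent, text):
    t = ET.SubElement(parent, "title")
    t.text = text
    return t


def _triangle_points(x, y, r):
    pts = [(x, y - r), (x - r * math.sin(math.pi / 3), y + r / 2),
           (x + r * math.sin(math.pi / 3), y + r / 2)]
    return " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)


def _diamond_points(x, y, r):
    pts = [(x, y - r), (x + r, y), (x, y + r), (x - r, y)]
    return " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)


def render_frame(
    diagram: Diagram,
    frame_styles: dict[str, dict[str, str]],
    tier: int,
    network: MetabolicNetwork | None = None,
) -> str:
    """Render one painted frame at a zoom tier; returns the SVG text.

    Glyphs whose ``min_zoom_tier`` exceeds the tier are omitted.  At tier 3,
    metabolite shapes are replaced by metabolite names whose text fill is the
    node's omics color, and gene labels appear next to reaction edges.
    """
    w, h = diagram.extent
    root = ET.Element("svg", {
        "xmlns": SVG_NS,
        "viewBox": f"0 0 {_fmt(w)} {_fmt(h)}",
        "width": _fmt(w),
        "height": _fmt(h),
    })
    seen_ids: dict[str, int] = {}
    for g in diagram.glyphs:
        if g.min_zoom_tier > tier:
            continue
        _emit_glyph(root, g, frame_styles, tier, network, seen_ids)
    return ET.tostring(root, encoding="unicode")


def _unique_id(seen: dict[str, int], ref: str) -> str:
    base = sanitize_id(ref)
    n = seen.get(base, 0)
    seen[base] = n + 1
    return base if n == 0 else f"{base}__{n + 1}"


def _emit_glyph(root, g: Glyph, styles, tier, network, seen_ids) -> None:
    if g.kind == "membrane":
        _el(root, "polyline", id="membrane",
            points=" ".join(f"{x:.2f},{y:.2f}" for x, y in g.points),
            fill="none", stroke="#8a6d3b", stroke_width="4")
        return
    if g.kind in ("region_label", "pathway_label"):
        x, y = g.points[0]
        e = _el(root, "text", x=_fmt(x), y=_fmt(y),
                text_anchor="middle",
                font_size="14" if g.kind == "region_label" else "9",
                fill="#333333")
        e.text = g.text or ""
        return
    if g.kind == "reaction_edge":
        style = styles.get(g.ref_id, {})
        eid = _unique_id(seen_ids, g.ref_id)
        e = _el(root, "polyline", id=eid,
                points=" ".join(f"{x:.2f},{y:.2f}" for x, y in g.points),
                fill="none",
                stroke=style.get("stroke", NEUTRAL_EDGE["stroke"]),
                stroke_width=style.get("stroke-width", NEUTRAL_EDGE["stroke-width"]))
        e.set("data-ref", g.ref_id)
        name = g.ref_id
        if network is not None and g.ref_id in network.reactions:
            rx = network.reactions[g.ref_id]
            if rx.enzyme_names:
                name = f"{g.ref_id} ({rx.enzyme_names[0]})"
        _title(e, name)
        if tier >= 3 and network is not None and g.ref_id in network.reactions:
            genes = network.reactions[g.ref_id].gene_ids
            if genes:
                mx = sum(p[0] for p in g.points) / len(g.points)
                my = sum(p[1] for p in g.points) / len(g.points)
                t = _el(root, "text", x=_fmt(mx + 4), y=_fmt(my),
                        font_size="6", fill="#555555")
                t.set("class", "gene-label")
                t.text = ",".join(genes)
        return
    if g.kind == "compound_node":
        style = styles.get(g.ref_id, {})
        x, y = g.points[0]
        fill = style.get("fill", SHADE_FILL if g.shaded else NEUTRAL_NODE_FILL)
        stroke_w = style.get("stroke-width", "1")
        name = g.ref_id
        if network is not None and g.ref_id in network.compounds:
            name = network.compounds[g.ref_id].name
        eid = _unique_id(seen_ids, g.ref_id)
        if tier >= 3:
            # semantic zoom: the shape gives way to the compound name,
            # colored with the node's omics data
            e = _el(root, "text", id=eid, x=_fmt(x), y=_fmt(y),
                    text_anchor="middle", font_size="7",
                    fill=style.get("fill", "#222222"))
            e.set("data-ref", g.ref_id)
            e.text = name
            _title(e, name)
            return
        common = dict(id=eid, fill=fill, stroke=NODE_OUTLINE, stroke_width=stroke_w)
        if g.shape == "triangle":
            e = _el(root, "polygon", points=_triangle_points(x, y, g.size), **common)
        elif g.shape == "square":
            e = _el(root, "rect", x=_fmt(x - g.size), y=_fmt(y - g.size),
                    width=_fmt(2 * g.size), height=_fmt(2 * g.size), **common)
        elif g.shape == "diamond":
            e = _el(root, "polygon", points=_diamond_points(x, y, g.size), **common)
        else:
            e = _el(root, "circle", cx=_fmt(x), cy=_fmt(y), r=_fmt(g.size), **common)
        e.set("data-ref", g.ref_id)
        _title(e, name)


def render_animation(
    diagram: Diagram,
    frameset: FrameSet,
    tier: int,
    out_dir,
    network: MetabolicNetwork | None = None,
    prefix: str = "frame",
) -> list[str]:
    """Write one SVG per frame plus ``index.json``; returns the file names.

    All frames share byte-identical geometry; only presentation attributes
    differ.  Documents are rendered fully in memory before any file is
    written, so a failure never leaves partial output.
    """
    docs = [
        render_frame(diagram, styles, tier, network) for styles in frameset.frames
    ]
    names = [f"{prefix}_{i:03d}.svg" for i in range(len(docs))]
    index = {
        "n_frames": frameset.n_frames,
        "frames": [
            {"file": name, "label": label}
            for name, label in zip(names, frameset.frame_labels)
        ],
    }
    os.makedirs(out_dir, exist_ok=True)
    for name, doc in zip(names, docs):
        with open(os.path.join(out_dir, name), "w", encoding="utf-8") as fh:
            fh.write(doc)
    with open(os.path.join(out_dir, "index.json"), "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=1)
    return names


# -- legend ---------------------------------------------------------------


def render_legend(histogram: HistogramSummary, state: ChannelState) -> str:
    """Histogram legend: one region per bin, boundary labels, per-bin counts."""
    k = state.breakpoints.n_bins
    if len(histogram.bin_counts) != k:
        raise ValueError(
            f"histogram has {len(histogram.bin_counts)} bins, state has {k}"
        )
    region_h, region_w, pad = 24.0, 60.0, 6.0
    width = region_w + 150
    height = k * region_h + 2 * pad + 16
    root = ET.Element("svg", {
        "xmlns": SVG_NS, "width": _fmt(width), "height": _fmt(height),
        "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
    })
    max_count = max(histogram.bin_counts) or 1
    bounds = state.breakpoints.boundaries
    # highest bin drawn on top, mirroring a vertical axis
    for i in range(k - 1, -1, -1):
        y = pad + (k - 1 - i) * region_h
        if state.is_color:
            _el(root, "rect", x=_fmt(pad), y=_fmt(y), width=_fmt(region_w),
                height=_fmt(region_h), fill=state.color_scale.colors[i],
                stroke="#333333", stroke_width="0.5",
                **{"class": "legend-bin"})
        else:
            mid = (bounds[i] + bounds[i + 1]) / 2
            wpx = value_to_thickness(mid, state)
            ln = _el(root, "line", x1=_fmt(pad), y1=_fmt(y + region_h / 2),
                     x2=_fmt(pad + region_w), y2=_fmt(y + region_h / 2),
                     stroke="#333333", stroke_width=_fmt_width(wpx))
            ln.set("class", "legend-bin")
        bar = histogram.bin_counts[i] / max_count * 60.0
        _el(root, "rect", x=_fmt(pad + region_w + 46), y=_fmt(y + 4),
            width=_fmt(max(bar, 0.5)), height=_fmt(region_h - 8), fill="#777777")
        cnt = _el(root, "text", x=_fmt(pad + region_w + 46 + 62), y=_fmt(y + region_h / 2 + 3),
                  font_size="8", fill="#222222")
        cnt.set("class", "bin-count")
        cnt.text = str(histogram.bin_counts[i])
    for i, b in enumerate(bounds):
        y = pad + (k - i) * region_h
        t = _el(root, "text", x=_fmt(pad + region_w + 4), y=_fmt(y + 3),
                font_size="8", fill="#222222")
        t.set("class", "boundary-label")
        t.text = f"{b:.2f}"
    return ET.tostring(root, encoding="unicode")


# -- omics popups ----------------------------------------------------------


def render_popup(
    target_id: str,
    experiment: MultiOmicsExperiment,
    network: MetabolicNetwork,
) -> str:
    """Per-entity plot of every contributing row of every dataset, pre-aggregation.

    A reaction popup shows each catalyzing gene's series from each dataset
    separately — the point is to compare isozymes, not their aggregate.
    Markers carry ``data-value`` attributes with the exact stored numbers.
    """
    series: list[tuple[str, list[str], list[float | None]]] = []
    for ds in experiment.datasets:
        for token, raw in ds.table.rows:
            if target_id in network.lookup_entity(token, ds.spec.data_type):
                series.append(
                    (f"{ds.spec.label}: {token}", ds.selected_labels(),
                     ds.selected_values(raw))
                )
    if not series:
        raise NoDataError(f"no omics data touches {target_id!r}")

    w, h = 360.0, 220.0
    m_left, m_right, m_top, m_bot = 48.0, 120.0, 24.0, 36.0
    plot_w, plot_h = w - m_left - m_right, h - m_top - m_bot
    all_vals = [v for _, _, vals in series for v in vals if v is not None]
    vmin = min(all_vals + [0.0])
    vmax = max(all_vals + [0.0])
    if vmax == vmin:
        vmax = vmin + 1.0
    n_cols = max(len(vals) for _, _, vals in series)

    def sx(i):
        return m_left + (i + 0.5) / n_cols * plot_w

    def sy(v):
        return m_top + (1 - (v - vmin) / (vmax - vmin)) * plot_h

    root = ET.Element("svg", {
        "xmlns": SVG_NS, "width": _fmt(w), "height": _fmt(h),
        "viewBox": f"0 0 {_fmt(w)} {_fmt(h)}",
    })
    title = _el(root, "text", x=_fmt(w / 2 - m_right / 2), y="14",
                text_anchor="middle", font_size="11", fill="#111111")
    title.text = _display_name(target_id, network)
    _el(root, "line", x1=_fmt(m_left), y1=_fmt(m_top + plot_h),
        x2=_fmt(m_left + plot_w), y2=_fmt(m_top + plot_h),
        stroke="#333333", stroke_width="1")
    _el(root, "line", x1=_fmt(m_left), y1=_fmt(m_top),
        x2=_fmt(m_left), y2=_fmt(m_top + plot_h), stroke="#333333", stroke_width="1")
    for v in (vmin, 0.0, vmax):
        t = _el(root, "text", x=_fmt(m_left - 4), y=_fmt(sy(v) + 3),
                text_anchor="end", font_size="7", fill="#444444")
        t.text = f"{v:.2f}"

    palette = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02"]
    x_labels = max(series, key=lambda s: len(s[2]))[1]
    for i, lbl in enumerate(x_labels):
        t = _el(root, "text", x=_fmt(sx(i)), y=_fmt(h - m_bot + 14),
                text_anchor="middle", font_size="7", fill="#444444")
        t.set("class", "x-label")
        t.text = lbl
    for s_i, (label, _labels, vals) in enumerate(series):
        color = palette[s_i % len(palette)]
        grp = _el(root, "g")
        grp.set("class", "series")
        grp.set("data-label", label)
        pts = [(sx(i), sy(v)) for i, v in enumerate(vals) if v is not None]
        if len(pts) > 1:
            _el(grp, "polyline",
                points=" ".join(f"{x:.2f},{y:.2f}" for x, y in pts),
                fill="none", stroke=color, stroke_width="1.5")
        for i, v in enumerate(vals):
            if v is None:
                continue
            c = _el(grp, "circle", cx=_fmt(sx(i)), cy=_fmt(sy(v)), r="2.5",
                    fill=color)
            c.set("data-value", repr(v))
            c.set("data-column", str(i))
        lt = _el(root, "text", x=_fmt(w - m_right + 6),
                 y=_fmt(m_top + 10 + s_i * 12), font_size="7", fill=color)
        lt.set("class", "series-label")
        lt.text = label
    return ET.tostring(root, encoding="unicode")


def _display_name(target_id: str, network: MetabolicNetwork) -> str:
    if target_id in network.compounds:
        return network.compounds[target_id].name
    if target_id in network.reactions:
        rx = network.reactions[target_id]
        return f"{target_id} ({rx.enzyme_names[0]})" if rx.enzyme_names else target_id
    return target_id
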