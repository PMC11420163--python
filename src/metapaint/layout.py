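"""Organism-scale diagram layout.

A deliberately simple layout honoring the field's drawing conventions for
whole-metabolism charts: biosynthetic pathways on the left, catabolic on the
right, energy/other in the center, orphan reactions gridded in a far-right
zone, everything framed by a cell-membrane border, and pathways flowing
downward as chains of metabolite nodes connected by reaction edges.  It makes
no attempt at the published pathway-specific layout algorithms; the painting
layer is the point, and it only needs a deterministic, convention-respecting
canvas.

Coordinates are abstract units with the origin top-left and y growing
downward (SVG convention).  Semantic zoom is expressed per glyph through
``min_zoom_tier``:

===== =====================================================
tier  content
===== =====================================================
0     membrane + region labels
1     + pathway names
2     + node shapes, reaction edges
3     + metabolite names (replacing shapes), gene labels
===== =====================================================
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass

import networkx as nx

from .network import CompoundNode, MetabolicNetwork, Pathway

log = logging.getLogger(__name__)

GLYPH_KINDS = ("compound_node", "reaction_edge", "pathway_label", "region_label", "membrane")
SHAPES = ("circle", "triangle", "square", "diamond", "line", "polyline", "text")

# geometry constants (abstract units)
STEP_Y = 40.0  # vertical distance between chained metabolites
NODE_R = 6.0
CURRENCY_R = 3.0
PATHWAY_W = 110.0  # width of one pathway glyph column
PATHWAY_PAD = 18.0
REGION_GAP = 30.0
MARGIN = 40.0
ORPHAN_CELL_W = 90.0
ORPHAN_CELL_H = 70.0
SHELF_MAX_H = 520.0  # target shelf height before starting a new column

DEFAULT_TIER_THRESHOLDS = (0.25, 1.0, 3.0)

#: compounds drawn as small side nodes rather than chain nodes
DEFAULT_CURRENCY_IDS = frozenset(
    {
        "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
        "water", "h2o", "phosphate", "pi", "ppi", "proton", "h+", "co2",
    }
)


@dataclass
class Glyph:
    kind: str
    ref_id: str | None
    shape: str
    points: list[tuple[float, float]]
    shaded: bool = False
    min_zoom_tier: int = 2
    text: str | None = None
    size: float = NODE_R

    def __post_init__(self):
        if self.kind not in GLYPH_KINDS:
            raise ValueError(f"unknown glyph kind {self.kind!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        for x, y in self.points:
            if not (abs(x) < float("inf") and abs(y) < float("inf")):
                raise ValueError(f"non-finite coordinate in glyph {self.ref_id!r}")

    def translate(self, dx: float, dy: float) -> "Glyph":
        return Glyph(
            kind=self.kind,
            ref_id=self.ref_id,
            shape=self.shape,
            points=[(x + dx, y + dy) for x, y in self.points],
            shaded=self.shaded,
            min_zoom_tier=self.min_zoom_tier,
            text=self.text,
            size=self.size,
        )

    def bbox(self) -> tuple[float, float, float, float]:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        return min(xs), min(ys), max(xs), max(ys)


SIDES = ("left_biosynthesis", "center_other", "right_catabolism", "far_right_orphans")


@dataclass
class DiagramRegion:
    category_path: list[str]
    side: str
    box: tuple[float, float, float, float]  # x0, y0, x1, y1

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.box
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass
class Diagram:
    glyphs: list[Glyph]
    regions: list[DiagramRegion]
    extent: tuple[float, float]
    tier_thresholds: tuple[float, ...] = DEFAULT_TIER_THRESHOLDS

    def reaction_edge_ids(self) -> set[str]:
        return {g.ref_id for g in self.glyphs if g.kind == "reaction_edge"}

    def compound_node_ids(self) -> set[str]:
        return {g.ref_id for g in self.glyphs if g.kind == "compound_node"}


# -- conventions -----------------------------------------------------------


def categorize_pathway(pathway: Pathway) -> str:
    """Map a pathway's top-level category to its diagram side."""
    top = pathway.category_path[0]
    if top == "biosynthesis":
        return "left_biosynthesis"
    if top == "degradation":
        return "right_catabolism"
    return "center_other"


_SHAPE_BY_CLASS = {
    "amino_acid": "triangle",
    "carbohydrate": "square",
    "nucleotide": "diamond",
    "lipid": "circle",
    "cofactor": "circle",
    "other": "circle",
}


def compound_glyph_shape(compound: CompoundNode) -> tuple[str, bool]:
    """Node shape conventions: triangles = amino acids, squares = carbohydrates,
    diamonds = nucleotides; shading marks phosphorylated compounds."""
    return _SHAPE_BY_CLASS[compound.compound_class], compound.phosphorylated


def zoom_tier_for_scale(scale: float, thresholds=DEFAULT_TIER_THRESHOLDS) -> int:
    """Detail tier for a magnification factor; monotone nondecreasing in scale."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return bisect_right(sorted(thresholds), scale)


# -- pathway-local layout --------------------------------------------------


def _order_reactions(pathway: Pathway, network: MetabolicNetwork) -> list[str]:
    """Order reactions by substrate->product chaining.

    A reaction whose product feeds another's substrate precedes it.  Kahn's
    algorithm with the pathway's stored order as tie-break; cycles are broken
    by releasing the earliest-stored remaining reaction.
    """
    rids = [rid for rid in pathway.reaction_ids if rid in network.reactions]
    pos = {rid: i for i, rid in enumerate(rids)}
    g = nx.DiGraph()
    g.add_nodes_from(rids)
    for a in rids:
        prods = set(network.reactions[a].product_ids)
        for b in rids:
            if a != b and prods & set(network.reactions[b].substrate_ids):
                g.add_edge(a, b)
    order: list[str] = []
    indeg = {n: g.in_degree(n) for n in rids}
    remaining = set(rids)
    while remaining:
        ready = sorted((n for n in remaining if indeg[n] == 0), key=pos.__getitem__)
        nxt = ready[0] if ready else min(remaining, key=pos.__getitem__)  # cycle break
        order.append(nxt)
        remaining.discard(nxt)
        for _, m in g.out_edges(nxt):
            if m in remaining:
                indeg[m] -= 1
    return order


def _main_compound(ids: list[str], currency: frozenset[str]) -> str | None:
    non_currency = [c for c in ids if c.casefold() not in currency]
    if non_currency:
        return non_currency[0]
    return ids[0] if ids else None


def layout_pathway(
    pathway: Pathway,
    network: MetabolicNetwork,
    currency_ids: frozenset[str] = DEFAULT_CURRENCY_IDS,
) -> list[Glyph]:
    """Lay out one pathway in local coordinates as a downward-flowing chain.

    Each reaction contributes one edge glyph and node glyphs for its main
    substrate and product; shared intermediates are drawn once; currency
    metabolites become small side nodes next to their reaction's edge.
    """
    order = _order_reactions(pathway, network)
    if not order:
        log.warning("pathway %r is empty", pathway.id)
        return []
    glyphs: list[Glyph] = [
        Glyph(
            kind="pathway_label",
            ref_id=pathway.id,
            shape="text",
            points=[(PATHWAY_W / 2, 0.0)],
            text=pathway.name,
            min_zoom_tier=1,
        )
    ]
    x_mid = PATHWAY_W / 2
    placed: dict[str, tuple[float, float]] = {}
    y = PATHWAY_PAD + STEP_Y / 2

    def place_node(cid: str, at_y: float) -> tuple[float, float]:
        if cid in placed:
            return placed[cid]
        comp = network.compounds[cid]
        shape, shaded = compound_glyph_shape(comp)
        placed[cid] = (x_mid, at_y)
        glyphs.append(
            Glyph(
                kind="compound_node",
                ref_id=cid,
                shape=shape,
                points=[(x_mid, at_y)],
                shaded=shaded,
                min_zoom_tier=2,
            )
        )
        return placed[cid]

    for rid in order:
        rx = network.reactions[rid]
        sub = _main_compound(rx.substrate_ids, currency_ids)
        prod = _main_compound(rx.product_ids, currency_ids)
        p_sub = place_node(sub, y) if sub else (x_mid, y)
        y_next = max(y, p_sub[1]) + STEP_Y
        p_prod = place_node(prod, y_next) if prod else (x_mid, y_next)
        glyphs.append(
            Glyph(
                kind="reaction_edge",
                ref_id=rid,
                shape="polyline" if p_sub[0] != p_prod[0] else "line",
                points=[p_sub, p_prod],
                min_zoom_tier=2,
            )
        )
        # every other participant (currency or co-substrate) becomes a small
        # side node so all compounds of a placed reaction stay paintable
        mid_y = (p_sub[1] + p_prod[1]) / 2
        side_x = x_mid + NODE_R * 3
        for cid in [*rx.substrate_ids, *rx.product_ids]:
            if cid not in placed:
                placed[cid] = (side_x, mid_y)
                comp = network.compounds[cid]
                shape, shaded = compound_glyph_shape(comp)
                glyphs.append(
                    Glyph(
                        kind="compound_node",
                        ref_id=cid,
                        shape=shape,
                        points=[(side_x, mid_y)],
                        shaded=shaded,
                        min_zoom_tier=2,
                        size=CURRENCY_R,
                    )
                )
                side_x += CURRENCY_R * 3
        y = max(y + STEP_Y, p_prod[1])
    return glyphs


# -- whole-network layout --------------------------------------------------


def _glyphs_bbox(glyphs: list[Glyph]) -> tuple[float, float, float, float]:
    boxes = [g.bbox() for g in glyphs]
    return (
        min(b[0] for b in boxes),
        min(b[1] for b in boxes),
        max(b[2] for b in boxes),
        max(b[3] for b in boxes),
    )


def _shelf_pack(items: list[tuple[str, float, float]]) -> tuple[dict[str, tuple[float, float]], float, float]:
    """Greedy column packing, tallest first; returns offsets and total w, h.

    Items are (key, width, height).  Deterministic: ties broken by key.
    """
    order = sorted(items, key=lambda it: (-it[2], it[0]))
    offsets: dict[str, tuple[float, float]] = {}
    col_x = 0.0
    col_w = 0.0
    cur_y = 0.0
    total_h = 0.0
    for key, w, h in order:
        if cur_y > 0 and cur_y + h > SHELF_MAX_H:
            col_x += col_w + PATHWAY_PAD
            col_w = 0.0
            cur_y = 0.0
        offsets[key] = (col_x, cur_y)
        cur_y += h + PATHWAY_PAD
        col_w = max(col_w, w)
        total_h = max(total_h, cur_y)
    return offsets, col_x + col_w, total_h


def layout_network(
    network: MetabolicNetwork,
    currency_ids: frozenset[str] = DEFAULT_CURRENCY_IDS,
    tier_thresholds=DEFAULT_TIER_THRESHOLDS,
) -> Diagram:
    """Lay out the whole network: packed pathway regions, orphan grid, membrane."""
    by_side: dict[str, list[Pathway]] = {s: [] for s in SIDES[:3]}
    for p in network.pathways.values():
        by_side[categorize_pathway(p)].append(p)

    local: dict[str, list[Glyph]] = {}
    dims: dict[str, tuple[float, float]] = {}
    for p in network.pathways.values():
        gl = layout_pathway(p, network, currency_ids)
        if not gl:
            continue
        x0, y0, x1, y1 = _glyphs_bbox(gl)
        local[p.id] = [g.translate(-x0 + NODE_R, -y0 + NODE_R) for g in gl]
        dims[p.id] = (max(x1 - x0, PATHWAY_W) + 2 * NODE_R, y1 - y0 + 2 * NODE_R)

    glyphs: list[Glyph] = []
    regions: list[DiagramRegion] = []
    x_cursor = MARGIN
    max_h = 0.0

    for side, label in [
        ("left_biosynthesis", "Biosynthesis"),
        ("center_other", "Energy / Other"),
        ("right_catabolism", "Degradation"),
    ]:
        members = sorted((p for p in by_side[side] if p.id in local), key=lambda p: p.id)
        if not members:
            continue
        offsets, w, h = _shelf_pack([(p.id, *dims[p.id]) for p in members])
        x0, y0 = x_cursor, MARGIN
        for p in members:
            ox, oy = offsets[p.id]
            glyphs.extend(g.translate(x0 + ox, y0 + oy) for g in local[p.id])
        regions.append(
            DiagramRegion(
                category_path=[label.lower().split(" ")[0]],
                side=side,
                box=(x0 - PATHWAY_PAD / 2, y0 - PATHWAY_PAD / 2,
                     x0 + w + PATHWAY_PAD / 2, y0 + h + PATHWAY_PAD / 2),
            )
        )
        glyphs.append(
            Glyph(
                kind="region_label",
                ref_id=None,
                shape="text",
                points=[(x0 + w / 2, MARGIN - PATHWAY_PAD)],
                text=label,
                min_zoom_tier=0,
            )
        )
        x_cursor += w + REGION_GAP
        max_h = max(max_h, h)

    orphans = sorted((r.id for r in network.orphan_reactions()))
    if orphans:
        n_rows = max(1, int(SHELF_MAX_H // ORPHAN_CELL_H))
        x0, y0 = x_cursor, MARGIN
        n_cols = (len(orphans) + n_rows - 1) // n_rows
        for i, rid in enumerate(orphans):
            col, row = divmod(i, n_rows)
            cx = x0 + col * ORPHAN_CELL_W + ORPHAN_CELL_W / 2
            cy = y0 + row * ORPHAN_CELL_H + ORPHAN_CELL_H / 2
            glyphs.extend(_orphan_glyphs(network, rid, cx, cy, currency_ids))
        w = n_cols * ORPHAN_CELL_W
        h = min(len(orphans), n_rows) * ORPHAN_CELL_H
        regions.append(
            DiagramRegion(
                category_path=["orphan"],
                side="far_right_orphans",
                box=(x0 - PATHWAY_PAD / 2, y0 - PATHWAY_PAD / 2,
                     x0 + w + PATHWAY_PAD / 2, y0 + h + PATHWAY_PAD / 2),
            )
        )
        glyphs.append(
            Glyph(
                kind="region_label",
                ref_id=None,
                shape="text",
                points=[(x0 + w / 2, MARGIN - PATHWAY_PAD)],
                text="Individual reactions",
                min_zoom_tier=0,
            )
        )
        x_cursor += w + REGION_GAP
        max_h = max(max_h, h)

    width = max(x_cursor - REGION_GAP + MARGIN, 2 * MARGIN + PATHWAY_W)
    height = max_h + 2 * MARGIN if max_h else 2 * MARGIN
    membrane = Glyph(
        kind="membrane",
        ref_id=None,
        shape="polyline",
        points=[
            (MARGIN / 2, MARGIN / 2),
            (width - MARGIN / 2, MARGIN / 2),
            (width - MARGIN / 2, height - MARGIN / 2),
            (MARGIN / 2, height - MARGIN / 2),
            (MARGIN / 2, MARGIN / 2),
        ],
        min_zoom_tier=0,
    )
    glyphs.insert(0, membrane)
    return Diagram(
        glyphs=glyphs,
        regions=regions,
        extent=(width, height),
        tier_thresholds=tuple(tier_thresholds),
    )


def _orphan_glyphs(network, rid, cx, cy, currency_ids) -> list[Glyph]:
    rx = network.reactions[rid]
    sub = _main_compound(rx.substrate_ids, currency_ids)
    prod = _main_compound(rx.product_ids, currency_ids)
    dy = ORPHAN_CELL_H / 2 - NODE_R * 1.5
    out: list[Glyph] = []
    top, bot = (cx, cy - dy), (cx, cy + dy)
    placed: set[str] = set()
    for cid, pt in [(sub, top), (prod, bot)]:
        if cid is None or cid in placed:
            continue
        placed.add(cid)
        comp = network.compounds[cid]
        shape, shaded = compound_glyph_shape(comp)
        out.append(
            Glyph(
                kind="compound_node",
                ref_id=cid,
                shape=shape,
                points=[pt],
                shaded=shaded,
                min_zoom_tier=2,
            )
        )
    side_x = cx + NODE_R * 2.5
    for cid in [*rx.substrate_ids, *rx.product_ids]:
        if cid in placed:
            continue
        placed.add(cid)
        comp = network.compounds[cid]
        shape, shaded = compound_glyph_shape(comp)
        out.append(
            Glyph(
                kind="compound_node",
                ref_id=cid,
                shape=shape,
                points=[(side_x, cy)],
                shaded=shaded,
                min_zoom_tier=2,
                size=CURRENCY_R,
            )
        )
        side_x += CURRENCY_R * 3
    out.append(
        Glyph(
            kind="reaction_edge",
            ref_id=rid,
            shape="line",
            points=[top, bot],
            min_zoom_tier=2,
        )
    )
    return out


# -- persistence -----------------------------------------------------------


def diagram_to_json(diagram: Diagram) -> str:
    return json.dumps(
        {
            "extent": list(diagram.extent),
            "tier_thresholds": list(diagram.tier_thresholds),
            "regions": [
                {"category_path": r.category_path, "side": r.side, "box": list(r.box)}
                for r in diagram.regions
            ],
            "glyphs": [
                {
                    "kind": g.kind,
                    "ref_id": g.ref_id,
                    "shape": g.shape,
                    "points": [list(p) for p in g.points],
                    "shaded": g.shaded,
                    "min_zoom_tier": g.min_zoom_tier,
                    "text": g.text,
                    "size": g.size,
                }
                for g in diagram.glyphs
            ],
        },
        indent=1,
    )


def diagram_from_json(text: str) -> Diagram:
    d = json.loads(text)
    return Diagram(
        glyphs=[
            Glyph(
                kind=g["kind"],
                ref_id=g["ref_id"],
                shape=g["shape"],
                points=[tuple(p) for p in g["points"]],
                shaded=g["shaded"],
                min_zoom_tier=g["min_zoom_tier"],
                text=g["text"],
                size=g["size"],
            )
            for g in d["glyphs"]
        ],
        regions=[
            DiagramRegion(
                category_path=r["category_path"], side=r["side"], box=tuple(r["box"])
            )
            for r in d["regions"]
        ],
        extent=tuple(d["extent"]),
        tier_thresholds=tuple(d["tier_thresholds"]),
    )
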