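"""Static SVG rendering of annotated trees and transition maps.

Output is plain SVG 1.1 text assembled deterministically (same inputs and
options give byte-identical documents).  Trees are drawn with branches
colored by the consensus reconstructed state; nodes where methods disagree
carry one bubble per method in root-to-tip reading order, and ambiguous
nodes can be drawn as posterior pie charts.  Transition maps are drawn in
rectangular, slanted, or radial layout with node size encoding the
collapse count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .f81 import MarginalPosteriors
from .transitions import TransitionMap, ambiguous_nodes, size_criterion
from .treedata import NodeAnnotationSet, PhyloTree

__all__ = ["RenderOptions", "render_tree", "render_map"]

# 20 visually distinct colors, cycled for auto-assignment (deterministic)
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)


@dataclass
class RenderOptions:
    layout: str = "rectangular"  # rectangular | slanted | radial
    colors: Dict[str, str] = field(default_factory=dict)
    pie_charts: bool = True
    ambiguity_fraction: float = 0.4
    background_sz: bool = False
    width: float = 800.0
    height: float = 600.0
    auto_palette: bool = True

    def color_of(self, state: str, order: Sequence[str]) -> str:
        if state in self.colors:
            return self.colors[state]
        if not self.auto_palette:
            raise ValueError(f"no color assigned for state {state!r}")
        return PALETTE[sorted(order).index(state) % len(PALETTE)]


def _fmt(x: float) -> str:
    return format(x, ".2f").rstrip("0").rstrip(".")


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _svg_document(body: List[str], width: float, height: float) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    return "\n".join([head, *body, "</svg>"]) + "\n"


def _legend(states: Sequence[str], options: RenderOptions, x: float, y: float) -> List[str]:
    out = ['<g class="legend">']
    for i, s in enumerate(sorted(states)):
        cy = y + 16 * i
        out.append(
            f'<circle cx="{_fmt(x)}" cy="{_fmt(cy)}" r="5" '
            f'fill="{options.color_of(s, states)}"/>'
        )
        out.append(
            f'<text x="{_fmt(x + 10)}" y="{_fmt(cy + 4)}" '
            f'font-size="11">{_esc(s)}</text>'
        )
    out.append("</g>")
    return out


def _pie(cx: float, cy: float, r: float, slices: Sequence[Tuple[str, float]]) -> List[str]:
    """Pie chart as SVG path sectors; slices are (color, fraction)."""
    out = [f'<g class="pie" transform="translate({_fmt(cx)},{_fmt(cy)})">']
    angle = -math.pi / 2
    for color, frac in slices:
        if frac <= 0:
            continue
        if frac >= 1.0 - 1e-9:
            out.append(f'<circle cx="0" cy="0" r="{_fmt(r)}" fill="{color}"/>')
            continue
        a2 = angle + 2 * math.pi * frac
        x1, y1 = r * math.cos(angle), r * math.sin(angle)
        x2, y2 = r * math.cos(a2), r * math.sin(a2)
        large = 1 if frac > 0.5 else 0
        out.append(
            f'<path d="M 0 0 L {_fmt(x1)} {_fmt(y1)} '
            f'A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x2)} {_fmt(y2)} Z" '
            f'fill="{color}"/>'
        )
        angle = a2
    out.append("</g>")
    return out


def _tree_layout(
    tree: PhyloTree, layout: str, width: float, height: float
) -> Dict[int, Tuple[float, float]]:
    """Node positions: x from root distance (unit steps when lengths are
    absent), leaves evenly spaced in y, internal nodes centered on children."""
    margin = 60.0
    if tree.has_branch_lengths():
        xdist = tree.depths()
    else:
        xdist = {}
        for node in tree.preorder():
            xdist[node.id] = 0.0 if node.parent is None else xdist[node.parent.id] + 1.0
    max_x = max(xdist.values()) or 1.0
    leaves = tree.leaves()
    ypos: Dict[int, float] = {}
    span = height - 2 * margin
    for i, leaf in enumerate(leaves):
        ypos[leaf.id] = margin + (span * i / max(len(leaves) - 1, 1))
    for node in tree.postorder():
        if not node.is_leaf:
            ypos[node.id] = sum(ypos[c.id] for c in node.children) / len(node.children)
    scale = (width - 2 * margin) / max_x
    return {
        n.id: (margin + xdist[n.id] * scale, ypos[n.id]) for n in tree.preorder()
    }


def render_tree(
    tree: PhyloTree,
    reconstructions: Mapping[str, NodeAnnotationSet],
    options: Optional[RenderOptions] = None,
    posteriors: Optional[MarginalPosteriors] = None,
) -> str:
    """Annotated-tree SVG with consensus coloring and disagreement bubbles.

    Branch color follows the (first-method) state when all methods agree at
    the child node; disagreeing nodes get one bubble per method, reading
    root-to-tips.  When ``posteriors`` are supplied and pie charts are
    enabled, ambiguous nodes (several states close to the MAP probability)
    are drawn as posterior pies.  Optional background shading encodes the
    Sz criterion.
    """
    options = options or RenderOptions()
    if not reconstructions:
        raise ValueError("need at least one reconstruction to render")
    methods = list(reconstructions)
    for name, states in reconstructions.items():
        states.require_full(tree)
    all_states = sorted(
        {s for states in reconstructions.values() for s in states.values()}
    )
    pos = _tree_layout(tree, options.layout, options.width, options.height)
    body: List[str] = ['<g class="tree" stroke-linecap="round">']

    if options.background_sz:
        sz = size_criterion(tree, reconstructions[methods[0]])
        max_sz = max(sz.values()) or 1
        for node in tree.preorder():
            if node.is_leaf:
                continue
            x, y = pos[node.id]
            shade = 0.15 + 0.55 * sz[node.id] / max_sz
            body.append(
                f'<circle class="sz" cx="{_fmt(x)}" cy="{_fmt(y)}" r="10" '
                f'fill="#000000" fill-opacity="{shade:.3f}" stroke="none"/>'
            )

    ambiguous = (
        ambiguous_nodes(posteriors, options.ambiguity_fraction)
        if (posteriors is not None and options.pie_charts)
        else {}
    )

    for node in tree.preorder():
        if node.parent is None:
            continue
        x0, y0 = pos[node.parent.id]
        x1, y1 = pos[node.id]
        node_states = [reconstructions[m][node.id] for m in methods]
        agree = len(set(node_states)) == 1
        color = options.color_of(node_states[0], all_states) if agree else "#555555"
        if options.layout == "slanted":
            body.append(
                f'<line x1="{_fmt(x0)}" y1="{_fmt(y0)}" x2="{_fmt(x1)}" '
                f'y2="{_fmt(y1)}" stroke="{color}" stroke-width="1.5"/>'
            )
        else:
            body.append(
                f'<path d="M {_fmt(x0)} {_fmt(y0)} V {_fmt(y1)} H {_fmt(x1)}" '
                f'fill="none" stroke="{color}" stroke-width="1.5"/>'
            )

    for node in tree.preorder():
        x, y = pos[node.id]
        node_states = [reconstructions[m][node.id] for m in methods]
        agree = len(set(node_states)) == 1
        if node.id in ambiguous and posteriors is not None:
            dist = posteriors.distribution(node.id)
            slices = [
                (options.color_of(s, all_states), dist[s])
                for s in sorted(dist, key=lambda s: (-dist[s], s))
                if dist[s] > 1e-9
            ]
            body.extend(_pie(x, y, 7.0, slices))
        elif not agree:
            # one bubble per method, root-to-tip reading order
            group = [f'<g class="bubbles" transform="translate({_fmt(x)},{_fmt(y)})">']
            for i, s in enumerate(node_states):
                group.append(
                    f'<circle cx="{_fmt(6.0 * i)}" cy="0" r="4" '
                    f'fill="{options.color_of(s, all_states)}" '
                    f'stroke="#000000" stroke-width="0.5"/>'
                )
            group.append("</g>")
            body.extend(group)
        if node.is_leaf:
            body.append(
                f'<text x="{_fmt(x + 6)}" y="{_fmt(y + 3)}" font-size="10">'
                f"{_esc(node.label or '')}</text>"
            )
    body.append("</g>")
    body.extend(_legend(all_states, options, options.width - 110, 30))
    return _svg_document(body, options.width, options.height)


def _map_layout(
    map_, layout: str, width: float, height: float
) -> Dict[int, Tuple[float, float]]:
    margin = 60.0
    nodes = map_.preorder()
    # x from cumulative distance for type-1 maps, tree depth otherwise
    if map_.map_type == 1:
        xdist = {n.id: n.distance for n in nodes}
    else:
        xdist = {}
        for n in nodes:
            xdist[n.id] = 0.0 if n.parent is None else xdist[n.parent.id] + 1.0
    max_x = max(xdist.values()) or 1.0
    tips = [n for n in nodes if not n.children]
    tpos: Dict[int, float] = {}
    for i, n in enumerate(tips):
        tpos[n.id] = i / max(len(tips) - 1, 1)
    for n in reversed(nodes):  # postorder-ish: children before parents
        if n.children:
            tpos[n.id] = sum(tpos[c.id] for c in n.children) / len(n.children)
    if layout == "radial":
        cx, cy = width / 2, height / 2
        rmax = min(width, height) / 2 - margin
        out = {}
        for n in nodes:
            r = rmax * xdist[n.id] / max_x
            a = 2 * math.pi * tpos[n.id] * 0.9
            out[n.id] = (cx + r * math.cos(a), cy + r * math.sin(a))
        return out
    span = height - 2 * margin
    scale = (width - 2 * margin) / max_x
    return {
        n.id: (margin + xdist[n.id] * scale, margin + span * tpos[n.id]) for n in nodes
    }


def render_map(
    map_: TransitionMap,
    options: Optional[RenderOptions] = None,
    shared: Optional[Dict[int, bool]] = None,
) -> str:
    """Transition-map SVG: nodes sized by collapse count, labeled
    ``state|count``; type-1 x positions are proportional to cumulative
    distance.  ``shared`` (from map compatibility) draws shared nodes with
    an orange outline.
    """
    options = options or RenderOptions()
    nodes = map_.preorder()
    states = sorted({n.state for n in nodes})
    pos = _map_layout(map_, options.layout, options.width, options.height)
    body: List[str] = [f'<g class="map type{map_.map_type}">']
    for n in nodes:
        if n.parent is None:
            continue
        x0, y0 = pos[n.parent.id]
        x1, y1 = pos[n.id]
        body.append(
            f'<line x1="{_fmt(x0)}" y1="{_fmt(y0)}" x2="{_fmt(x1)}" y2="{_fmt(y1)}" '
            f'stroke="#888888" stroke-width="1"/>'
        )
    for n in nodes:
        x, y = pos[n.id]
        r = 6.0 + 3.0 * math.sqrt(n.count - 1)
        outline = "#ff8c00" if (shared and shared.get(n.id)) else "#000000"
        owidth = "2.5" if (shared and shared.get(n.id)) else "0.8"
        body.append(
            f'<circle class="mapnode" cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(r)}" '
            f'fill="{options.color_of(n.state, states)}" '
            f'stroke="{outline}" stroke-width="{owidth}"/>'
        )
        body.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y - r - 3)}" font-size="10" '
            f'text-anchor="middle">{_esc(f"{n.state}|{n.count}")}</text>'
        )
    body.append("</g>")
    body.extend(_legend(states, options, options.width - 110, 30))
    return _svg_document(body, options.width, options.height)
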