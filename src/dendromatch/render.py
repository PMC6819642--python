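"""Deterministic static SVG rendering of dendrograms and their matches.

Each dendrogram is drawn as a rectangular-elbow tree in its own panel, with
a title, a distance axis (measured from the leaves), a dashed threshold
marker, leaf labels with replicate indicators, and — between consecutive
panels — one translucent colored connector per cluster match.  Output is
assembled as plain text with fixed number formatting, so identical inputs
produce byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import ClusterMatch, highlight_branches
from .newick_io import Dendrogram, DendroNode
from .replicate_model import DEFAULT_DELIMITER, parse_leaf_identity

#: categorical palette (10 distinguishable colors), cycled beyond that
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass
class LayoutSpec:
    """Geometry and display options for :func:`render_svg`.

    The panel height is derived from the dendrogram with the most leaves at
    a fixed minimum separation per leaf.
    """

    leaf_spacing: float = 18.0
    tree_width: float = 240.0
    label_width: float = 130.0
    panel_gap: float = 40.0
    margin: float = 30.0
    title_space: float = 24.0
    axis_space: float = 34.0
    highlight_mode: str = "none"  # equal | different | none
    show_matches: bool = True
    thresholds: dict[str, float] = field(default_factory=dict)
    delimiter: str = DEFAULT_DELIMITER


def _f(x: float) -> str:
    return f"{x:.2f}"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _positions(d: Dendrogram, layout: LayoutSpec, x0: float,
               y0: float) -> dict[int, tuple[float, float]]:
    """Node id → (x, y).  Leaves evenly spaced; x proportional to height."""
    pos: dict[int, tuple[float, float]] = {}
    leaves = d.root.leaves()
    h_max = d.root_height or 1.0
    flipped = d.orientation == "root-right"

    def x_of(height: float) -> float:
        frac = height / h_max
        return x0 + (frac if flipped else 1.0 - frac) * layout.tree_width

    for i, leaf in enumerate(leaves):
        pos[leaf.id] = (x_of(0.0), y0 + (i + 0.5) * layout.leaf_spacing)
    for node in d.root.walk_postorder():
        if not node.is_leaf:
            ys = [pos[c.id][1] for c in node.children]
            pos[node.id] = (x_of(node.height), (min(ys) + max(ys)) / 2.0)
    return pos


def render_svg(
    dendrograms: list[Dendrogram],
    pair_matches: list[list[ClusterMatch]] | None = None,
    layout: LayoutSpec | None = None,
) -> str:
    """Render dendrograms side by side with match connectors; returns SVG text."""
    layout = layout or LayoutSpec()
    pair_matches = pair_matches or []
    if not dendrograms:
        return ('<svg xmlns="http://www.w3.org/2000/svg" width="400" height="60">'
                '<text x="20" y="35" font-family="sans-serif">'
                'no dendrograms loaded</text></svg>')

    panel_w = layout.tree_width + layout.label_width
    max_leaves = max(d.leaf_count for d in dendrograms)
    tree_h = max_leaves * layout.leaf_spacing
    y0 = layout.margin + layout.title_space
    total_w = (layout.margin * 2 + panel_w * len(dendrograms)
               + layout.panel_gap * (len(dendrograms) - 1))
    total_h = y0 + tree_h + layout.axis_space + layout.margin

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(total_w)}" '
        f'height="{_f(total_h)}" font-family="sans-serif">',
    ]
    panel_pos: list[dict[int, tuple[float, float]]] = []
    panel_x: list[float] = []

    for i, d in enumerate(dendrograms):
        x0 = layout.margin + i * (panel_w + layout.panel_gap)
        flipped = d.orientation == "root-right"
        tree_x = x0 + (0.0 if not flipped else layout.label_width)
        pos = _positions(d, layout, tree_x, y0)
        panel_pos.append(pos)
        panel_x.append(tree_x)
        parts.append(f'<g class="dendrogram" data-title="{_esc(d.title)}">')
        parts.append(f'<text class="title" x="{_f(x0 + panel_w / 2)}" '
                     f'y="{_f(layout.margin)}" text-anchor="middle" '
                     f'font-size="13">{_esc(d.title)}</text>')
        # branches: one elbow path per edge (vertical to child's row, then across)
        for node in d.root.walk_postorder():
            for child in node.children:
                px, py = pos[node.id]
                cx, cy = pos[child.id]
                parts.append(f'<path class="branch" data-edge="{child.id}" '
                             f'd="M {_f(px)} {_f(py)} V {_f(cy)} H {_f(cx)}" '
                             f'fill="none" stroke="#444" stroke-width="1"/>')
        # leaf labels + replicate indicators
        for leaf in d.root.leaves():
            lx, ly = pos[leaf.id]
            anchor = "start" if not flipped else "end"
            dx = 10.0 if not flipped else -10.0
            ident = parse_leaf_identity(leaf.name or "", layout.delimiter)
            if ident.replicate_id is not None:
                parts.append(f'<circle class="replicate-indicator" '
                             f'cx="{_f(lx + dx / 2)}" cy="{_f(ly)}" r="2.5" '
                             f'fill="#999"/>')
            parts.append(f'<text class="leaf" x="{_f(lx + dx)}" '
                         f'y="{_f(ly + 3.5)}" text-anchor="{anchor}" '
                         f'font-size="11">{_esc(leaf.name or "")}</text>')
        # distance axis under the tree (distance measured from the leaves)
        ax_y = y0 + tree_h + 14.0
        h_max = d.root_height or 1.0
        parts.append(f'<path class="axis" d="M {_f(tree_x)} {_f(ax_y)} '
                     f'H {_f(tree_x + layout.tree_width)}" stroke="#000" '
                     f'stroke-width="1"/>')
        for k in range(5):
            frac = k / 4.0
            tx = tree_x + (frac if flipped else 1.0 - frac) * layout.tree_width
            parts.append(f'<path d="M {_f(tx)} {_f(ax_y)} V {_f(ax_y + 4)}" '
                         f'stroke="#000" stroke-width="1"/>')
            parts.append(f'<text x="{_f(tx)}" y="{_f(ax_y + 16)}" '
                         f'text-anchor="middle" font-size="9">'
                         f'{h_max * frac:.3g}</text>')
        # threshold marker
        thr = layout.thresholds.get(d.title, h_max / 2.0)
        frac = min(max(thr / h_max, 0.0), 1.0)
        tx = tree_x + (frac if flipped else 1.0 - frac) * layout.tree_width
        parts.append(f'<path class="threshold" d="M {_f(tx)} {_f(y0)} '
                     f'V {_f(y0 + tree_h)}" stroke="#c33" stroke-width="1" '
                     f'stroke-dasharray="4 3"/>')
        parts.append('</g>')

    # match connectors between consecutive panels, one color per match
    for i, matches in enumerate(pair_matches):
        if i + 1 >= len(dendrograms) or not layout.show_matches:
            break
        for m in matches:
            color = PALETTE[m.color_index % len(PALETTE)]
            sx, sy = panel_pos[i][m.source_node.id]
            tx, ty = panel_pos[i + 1][m.target_node.id]
            parts.append(f'<g class="match" data-color-index="{m.color_index}">')
            parts.append(f'<path class="match-connector" d="M {_f(sx)} {_f(sy)} '
                         f'L {_f(tx)} {_f(ty)}" stroke="{color}" '
                         f'stroke-width="6" stroke-opacity="0.45" fill="none"/>')
            if layout.highlight_mode in ("equal", "different"):
                if not m.equal_branches and not m.different_branches:
                    highlight_branches(m, layout.delimiter)
                chosen = (m.equal_branches if layout.highlight_mode == "equal"
                          else m.different_branches)
                for role, edge_id in sorted(chosen):
                    panel = i if role == "source" else i + 1
                    node = _find_node(dendrograms[panel], edge_id)
                    if node is None or node.parent is None:
                        continue
                    px, py = panel_pos[panel][node.parent.id]
                    cx, cy = panel_pos[panel][node.id]
                    parts.append(f'<path class="highlight" '
                                 f'd="M {_f(px)} {_f(py)} V {_f(cy)} H {_f(cx)}" '
                                 f'fill="none" stroke="{color}" '
                                 f'stroke-width="2.5"/>')
            parts.append('</g>')

    parts.append('</svg>')
    return "\n".join(parts)


def _find_node(d: Dendrogram, node_id: int) -> DendroNode | None:
    for node in d.root.walk_postorder():
        if node.id == node_id:
            return node
    return None
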