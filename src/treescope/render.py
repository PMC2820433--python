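"""Rule-driven static rendering of trees as ASCII (via the core) or SVG.

A layout rule is any callable ``node -> (NodeStyle, [Face])``; the renderer
walks the tree, asks the rule for each node's aspect and emits a
standalone, deterministic SVG document: same tree + same layout = byte
identical output.  Layout rules must not mutate the tree.

Two pre-defined layouts mirror the standard phylogenetic and clustering
views: ``phylo_layout`` paints duplication nodes blue, speciation nodes
red and loss leaves as dashed grey branches, attaching aligned sequence
strips to leaves; ``cluster_layout`` shows leaf profiles as heatmap rows
and draws a bubble per internal node whose size is proportional to the
absolute silhouette, green for positive and red for negative values.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .tree import TreeNode
from .clustering import PROFILE_FEATURE
from .phylo import DUPLICATION, LOSS_FEATURE, LOSS_VALUE, SPECIATION

#: categorical colour encodings; constants, not per-call values
THEME = {
    "duplication": "#0000ff",   # blue
    "speciation": "#ff0000",    # red
    "loss": "#999999",          # grey, drawn dashed
    "silhouette_pos": "#00aa00",  # green bubble
    "silhouette_neg": "#cc0000",  # red bubble
    "edge": "#000000",
    "text": "#000000",
    "neutral": "#333333",
}

_HEX = re.compile(r"^#[0-9a-fA-F]{6}$")
_NAMED = re.compile(r"^[a-zA-Z]+$")


class RenderError(Exception):
    """Raised when a layout rule fails or a style is invalid."""


def _check_color(color: str) -> str:
    if not (_HEX.match(color) or _NAMED.match(color)):
        raise RenderError(f"invalid colour {color!r}: use #rrggbb or a name")
    return color


@dataclass
class NodeStyle:
    """Per-node visual directives."""
    shape: str = "circle"            # circle | square | none
    size: float = 0.0                # symbol size in px
    fill_color: str = THEME["neutral"]
    line_style: str = "solid"        # solid | dashed
    line_color: str = THEME["edge"]
    visible: bool = True

    def __post_init__(self):
        if self.shape not in ("circle", "square", "none"):
            raise RenderError(f"invalid shape {self.shape!r}")
        if self.size < 0:
            raise RenderError("style size must be >= 0")
        if self.line_style not in ("solid", "dashed"):
            raise RenderError(f"invalid line style {self.line_style!r}")
        _check_color(self.fill_color)
        _check_color(self.line_color)


@dataclass
class Face:
    """A graphical item attached beside a node."""
    kind: str                        # text | sequence_strip | bar_graph |
                                     # heatmap_row | external_image
    payload: object = None
    position: str = "branch_right"   # branch_right | aligned_right | branch_top

    def __post_init__(self):
        kinds = ("text", "sequence_strip", "bar_graph", "heatmap_row",
                 "external_image")
        if self.kind not in kinds:
            raise RenderError(f"invalid face kind {self.kind!r}")
        if self.position not in ("branch_right", "aligned_right", "branch_top"):
            raise RenderError(f"invalid face position {self.position!r}")
        if self.kind == "text" and not self.payload:
            raise RenderError("text face needs a non-empty payload")


LayoutRule = Callable[[TreeNode], tuple[NodeStyle, Sequence[Face]]]


def basic_layout(node: TreeNode) -> tuple[NodeStyle, list[Face]]:
    """Plain dendrogram: thin black edges, no symbols, leaf names only."""
    return NodeStyle(shape="none"), []


# ----------------------------------------------------------- builtin layouts
def phylo_layout(node: TreeNode) -> tuple[NodeStyle, list[Face]]:
    """Evolutionary-events view: blue duplications, red speciations,
    dashed grey loss leaves, aligned sequence strips."""
    faces: list[Face] = []
    if node.features.get(LOSS_FEATURE) == LOSS_VALUE:
        style = NodeStyle(shape="none", line_style="dashed",
                          line_color=THEME["loss"])
        return style, faces
    event = getattr(node, "event", None)
    if event == DUPLICATION:
        style = NodeStyle(shape="circle", size=5.0,
                          fill_color=THEME["duplication"])
    elif event == SPECIATION:
        style = NodeStyle(shape="circle", size=5.0,
                          fill_color=THEME["speciation"])
    else:
        style = NodeStyle(shape="none")
    sequence = getattr(node, "sequence", None)
    if not node.children and sequence:
        faces.append(Face("sequence_strip", sequence, "aligned_right"))
    return style, faces


#: px of bubble radius per unit of |silhouette|
SILHOUETTE_BUBBLE_SCALE = 12.0


def cluster_layout(node: TreeNode) -> tuple[NodeStyle, list[Face]]:
    """Cluster-validation view: heatmap rows on leaves; on internal nodes a
    bubble of radius proportional to |silhouette|, green when positive and
    red when negative (hidden at exactly zero)."""
    faces: list[Face] = []
    if not node.children and PROFILE_FEATURE in node.features:
        faces.append(Face("heatmap_row",
                          list(map(float, node.features[PROFILE_FEATURE])),
                          "aligned_right"))
    sil = node.features.get("silhouette")
    if sil is None or not node.children:
        return NodeStyle(shape="none"), faces
    sil = float(sil)
    if sil == 0:
        return NodeStyle(shape="none", size=0.0, visible=False), faces
    colour = THEME["silhouette_pos"] if sil > 0 else THEME["silhouette_neg"]
    return NodeStyle(shape="circle", size=abs(sil) * SILHOUETTE_BUBBLE_SCALE,
                     fill_color=colour), faces


# ------------------------------------------------------------------ the SVG
_ROW_H = 20.0
_MARGIN = 12.0
_FONT = 10
_CELL_W = 6.0


def _f(x: float) -> str:
    return f"{x:.2f}"


def _esc(text: str) -> str:
    return (str(text).replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _heat_color(value: float, lo: float, hi: float) -> str:
    """Blue (low) - white - red (high) diverging map."""
    if hi <= lo:
        t = 0.5
    else:
        t = (value - lo) / (hi - lo)
    t = min(max(t, 0.0), 1.0)
    if t < 0.5:
        frac = t / 0.5
        r, g, b = int(255 * frac), int(255 * frac), 255
    else:
        frac = (t - 0.5) / 0.5
        r, g, b = 255, int(255 * (1 - frac)), int(255 * (1 - frac))
    return f"#{r:02x}{g:02x}{b:02x}"


_AA_COLORS = {
    "A": "#80a0f0", "R": "#f01505", "N": "#00ff00", "D": "#c048c0",
    "C": "#f08080", "Q": "#00ff00", "E": "#c048c0", "G": "#f09048",
    "H": "#15a4a4", "I": "#80a0f0", "L": "#80a0f0", "K": "#f01505",
    "M": "#80a0f0", "F": "#80a0f0", "P": "#ffff00", "S": "#00ff00",
    "T": "#00ff00", "W": "#80a0f0", "Y": "#15a4a4", "V": "#80a0f0",
    "-": "#ffffff", ".": "#ffffff",
}


def render_svg(root: TreeNode, layout: LayoutRule | None = None,
               width: float = 800.0, scale: float | None = None,
               align_leaves: bool = False) -> str:
    """Render the tree to a standalone SVG document string.

    Horizontal position is proportional to root-path length times
    ``scale`` (auto-fitted to half of ``width`` when omitted); leaves are
    stacked top to bottom in traversal order.  ``align_leaves`` right-
    aligns all leaves (ultrametric display, the usual choice for
    clustering trees).  Exceptions raised by the layout rule are wrapped
    with the offending node's identity.
    """
    layout = layout or basic_layout
    leaves = root.get_leaves()
    ypos: dict[int, float] = {}
    for i, leaf in enumerate(leaves):
        ypos[id(leaf)] = _MARGIN + (i + 0.5) * _ROW_H
    for node in root.traverse("postorder"):
        if node.children:
            ypos[id(node)] = (ypos[id(node.children[0])]
                              + ypos[id(node.children[-1])]) / 2.0

    xpos: dict[int, float] = {id(root): 0.0}
    for node in root.traverse("preorder"):
        if node.up is not None:
            xpos[id(node)] = xpos[id(node.up)] + node.dist
    max_depth = max(xpos.values()) or 1.0
    if scale is None:
        scale = (width * 0.5) / max_depth
    for key in xpos:
        xpos[key] *= scale
    x_leaf_max = max(xpos[id(l)] for l in leaves)

    styles: dict[int, NodeStyle] = {}
    faces: dict[int, list[Face]] = {}
    for node in root.traverse("preorder"):
        try:
            style, node_faces = layout(node)
        except Exception as exc:
            raise RenderError(
                f"layout rule failed at node {node.name!r}: {exc}") from exc
        styles[id(node)] = style
        faces[id(node)] = list(node_faces)

    def display_x(node: TreeNode) -> float:
        if align_leaves and not node.children:
            return x_leaf_max
        return xpos[id(node)]

    body: list[str] = []
    aligned_x0 = x_leaf_max + 80.0  # room for leaf labels
    max_x_used = aligned_x0

    for node in root.traverse("preorder"):
        st = styles[id(node)]
        x, y = display_x(node), ypos[id(node)]
        if node.up is not None:
            px = xpos[id(node.up)]
            dash = ' stroke-dasharray="4,2"' if st.line_style == "dashed" else ""
            body.append(
                f'<line x1="{_f(px)}" y1="{_f(y)}" x2="{_f(x)}" y2="{_f(y)}" '
                f'stroke="{st.line_color}" stroke-width="1"{dash}/>')
        if node.children:
            y0 = ypos[id(node.children[0])]
            y1 = ypos[id(node.children[-1])]
            body.append(
                f'<line x1="{_f(x)}" y1="{_f(y0)}" x2="{_f(x)}" y2="{_f(y1)}" '
                f'stroke="{st.line_color}" stroke-width="1"/>')
        if st.visible and st.shape != "none" and st.size > 0:
            if st.shape == "circle":
                body.append(
                    f'<circle cx="{_f(x)}" cy="{_f(y)}" r="{_f(st.size)}" '
                    f'fill="{st.fill_color}"/>')
            else:
                s = st.size
                body.append(
                    f'<rect x="{_f(x - s)}" y="{_f(y - s)}" '
                    f'width="{_f(2 * s)}" height="{_f(2 * s)}" '
                    f'fill="{st.fill_color}"/>')
        if not node.children and node.name:
            body.append(
                f'<text x="{_f(x + 4)}" y="{_f(y + _FONT / 2 - 1)}" '
                f'font-size="{_FONT}" font-family="monospace" '
                f'fill="{THEME["text"]}" class="leaf-name">'
                f'{_esc(node.name)}</text>')
        # faces
        x_branch = x + 4 + (len(node.name) + 1) * _FONT * 0.62 \
            if not node.children else x + 4
        for face in faces[id(node)]:
            if face.position == "aligned_right":
                fx = aligned_x0
            elif face.position == "branch_top":
                fx = (xpos[id(node.up)] + x) / 2 if node.up else x
            else:
                fx = x_branch
            fy = y - _ROW_H / 2 if face.position != "branch_top" else y - 12
            used = _emit_face(body, face, fx, fy, y)
            max_x_used = max(max_x_used, fx + used)

    height = 2 * _MARGIN + len(leaves) * _ROW_H
    total_w = max(width, max_x_used + _MARGIN)
    head = (f'<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{_f(total_w)}" height="{_f(height)}" '
            f'viewBox="0 0 {_f(total_w)} {_f(height)}">')
    return head + "".join(body) + "</svg>"


def _emit_face(body: list[str], face: Face, fx: float, fy: float,
               ycenter: float) -> float:
    """Append SVG for one face; returns the horizontal extent used."""
    if face.kind == "text":
        text = _esc(face.payload)
        body.append(f'<text x="{_f(fx)}" y="{_f(ycenter + _FONT / 2 - 1)}" '
                    f'font-size="{_FONT}" font-family="monospace" '
                    f'class="face-text">{text}</text>')
        return len(str(face.payload)) * _FONT * 0.62
    if face.kind == "sequence_strip":
        seq = str(face.payload)
        for i, ch in enumerate(seq):
            color = _AA_COLORS.get(ch.upper(), "#cccccc")
            body.append(f'<rect x="{_f(fx + i * _CELL_W)}" '
                        f'y="{_f(ycenter - 5)}" width="{_f(_CELL_W)}" '
                        f'height="10" fill="{color}" class="seq-cell"/>')
        return len(seq) * _CELL_W
    if face.kind == "heatmap_row":
        values = [float(v) for v in face.payload]
        finite = [v for v in values if v == v]
        lo = min(finite) if finite else 0.0
        hi = max(finite) if finite else 0.0
        for i, v in enumerate(values):
            color = _heat_color(v, lo, hi) if v == v else "#eeeeee"
            body.append(f'<rect x="{_f(fx + i * _CELL_W)}" '
                        f'y="{_f(ycenter - 7)}" width="{_f(_CELL_W)}" '
                        f'height="14" fill="{color}" class="heat-cell"/>')
        return len(values) * _CELL_W
    if face.kind == "bar_graph":
        values = [float(v) for v in face.payload]
        top = max((abs(v) for v in values), default=1.0) or 1.0
        for i, v in enumerate(values):
            h = abs(v) / top * 14.0
            body.append(f'<rect x="{_f(fx + i * _CELL_W)}" '
                        f'y="{_f(ycenter + 7 - h)}" width="{_f(_CELL_W - 1)}" '
                        f'height="{_f(h)}" fill="#555555" class="bar-cell"/>')
        return len(values) * _CELL_W
    # external_image
    href = _esc(face.payload)
    body.append(f'<image x="{_f(fx)}" y="{_f(ycenter - 8)}" width="16" '
                f'height="16" href="{href}"/>')
    return 16.0
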