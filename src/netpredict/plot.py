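"""Network visualization with predictability rings.

Each node carries a donut ring: continuous nodes a blue segment whose
fraction is R^2; categorical nodes an orange segment (marginal-model
accuracy) followed by a red segment (additional accuracy contributed by the
neighbors), the white remainder being 1 - CC.  The normalized accuracy is
then the visual ratio red / (red + white).  Edges are green when positive,
red when negative, grey when the sign is undefined, with width proportional
to |weight|.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.patches import FancyArrowPatch, Wedge

from .predictability import PredictabilityReport

BLUE = "#3c7fb8"
ORANGE = "#ff9e27"
RED = "#d7191c"
EDGE_POS = "#1a9641"
EDGE_NEG = "#d7191c"
EDGE_UNDEF = "#999999"


@dataclass
class RingSpec:
    """Ordered (fraction, color) segments per node; the remainder up to 1 is
    drawn as an empty white ring."""

    segments: list[list[tuple[float, str]]]
    clipped: list[int]

    def fractions(self, node: int) -> list[float]:
        return [f for f, _ in self.segments[node]]


def build_rings(report: PredictabilityReport) -> RingSpec:
    """Map a predictability report to ring segments.

    Continuous node: one blue segment of fraction R^2, clipped into [0, 1]
    for display (clipping recorded in ``clipped``).  Categorical node:
    orange CCmarg then red CC - CCmarg.
    """
    segments = []
    clipped = []
    for m in report.nodes:
        if m.family == "categorical":
            extra = m.CC - m.CCmarg
            if extra < 0:
                clipped.append(m.node)
                extra = 0.0
            segments.append([(float(m.CCmarg), ORANGE), (float(extra), RED)])
        else:
            r2 = m.R2
            if r2 < 0 or r2 > 1:
                clipped.append(m.node)
                r2 = min(max(r2, 0.0), 1.0)
            segments.append([(float(r2), BLUE)])
    for segs in segments:
        if sum(f for f, _ in segs) > 1 + 1e-9:
            raise ValueError("ring segment fractions exceed 1")
    return RingSpec(segments=segments, clipped=clipped)


def _edge_color(sign: float) -> str:
    if np.isnan(sign):
        return EDGE_UNDEF
    if sign > 0:
        return EDGE_POS
    if sign < 0:
        return EDGE_NEG
    return EDGE_UNDEF


def to_graph(model, rings: RingSpec | None = None) -> "nx.Graph":
    """networkx graph (directed for VAR models) with weight/sign edge
    attributes and ring fractions as node attributes."""
    directed = getattr(model, "kind", "mgm") == "mvar"
    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for s, spec in enumerate(model.specs):
        attrs = {"label": spec.name, "family": spec.family}
        if rings is not None:
            for i, (frac, color) in enumerate(rings.segments[s]):
                attrs[f"ring{i}_fraction"] = float(frac)
                attrs[f"ring{i}_color"] = color
        G.add_node(s, **attrs)
    idx = np.argwhere(model.weights > 0)
    for i, j in idx:
        if not directed and i >= j:
            continue
        sg = model.signs[i, j]
        G.add_edge(int(i), int(j), weight=float(model.weights[i, j]),
                   sign="undefined" if np.isnan(sg) else int(sg))
    return G


def plot_network(
    model,
    rings: RingSpec,
    layout: str = "spring",
    seed: int = 1,
    out: str | None = None,
    graphml: str | None = None,
    node_size: float = 0.09,
    max_width: float = 6.0,
    labels: bool = True,
):
    """Render the network to PNG/SVG and optionally export GraphML.

    Spring (Fruchterman-Reingold) layout is seeded so repeated runs are
    identical; node distances carry no model meaning.  Returns the
    matplotlib figure.
    """
    G = to_graph(model, rings)
    directed = G.is_directed()
    if layout == "spring":
        pos = nx.spring_layout(G, seed=seed)
    elif layout == "circle":
        pos = nx.circular_layout(G)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.set_aspect("equal")
    ax.axis("off")

    wmax = max((d["weight"] for _, _, d in G.edges(data=True)), default=1.0)
    for u, v, d in G.edges(data=True):
        color = _edge_color(np.nan if d["sign"] == "undefined" else d["sign"])
        lw = max_width * d["weight"] / wmax
        if u == v:
            # self-loop: small circle tangent to the node
            x, y = pos[u]
            loop = plt.Circle((x, y + node_size * 1.6), node_size * 0.9,
                              fill=False, color=color, lw=lw)
            ax.add_patch(loop)
            continue
        if directed:
            arrow = FancyArrowPatch(
                pos[u], pos[v], arrowstyle="-|>", mutation_scale=12,
                color=color, lw=lw, shrinkA=18, shrinkB=18,
                connectionstyle="arc3,rad=0.08", zorder=1,
            )
            ax.add_patch(arrow)
        else:
            ax.plot(*zip(pos[u], pos[v]), color=color, lw=lw, zorder=1)

    ring_width = node_size * 0.38
    for s in G.nodes:
        x, y = pos[s]
        theta = 90.0
        for frac, color in rings.segments[s]:
            if frac <= 0:
                continue
            ax.add_patch(Wedge((x, y), node_size, theta - 360.0 * frac, theta,
                               width=ring_width, facecolor=color,
                               edgecolor="none", zorder=3))
            theta -= 360.0 * frac
        ax.add_patch(Wedge((x, y), node_size, theta - 360.0 *
                           max(0.0, 1.0 - sum(rings.fractions(s))), theta,
                           width=ring_width, facecolor="white",
                           edgecolor="0.6", lw=0.4, zorder=2))
        ax.add_patch(plt.Circle((x, y), node_size - ring_width,
                                facecolor="#f2f2f2", edgecolor="0.4",
                                lw=0.6, zorder=4))
        if labels:
            ax.text(x, y, model.specs[s].name, ha="center", va="center",
                    fontsize=8, zorder=5)

    margin = 0.25
    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    ax.set_xlim(min(xs) - margin, max(xs) + margin)
    ax.set_ylim(min(ys) - margin, max(ys) + margin)

    if out is not None:
        fig.savefig(out, bbox_inches="tight", dpi=150)
    if graphml is not None:
        nx.write_graphml(G, graphml)
    return fig
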