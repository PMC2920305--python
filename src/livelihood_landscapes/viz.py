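"""Draw livelihood-landscape maps and export networks to graph formats.

The drawing conventions follow the field's map style: node area scales with
the number of households reporting the occupation; each node is a two-wedge
pie whose shaded fraction is the share of those households ranking it
primary; directed arrows run from higher- to lower-ranked occupations with
width proportional to link weight; links below the 5% weight threshold are
not drawn.  Node positions come from a seeded spring embedding of the pruned
weighted graph, so an occupation linked evenly to all others lands near the
middle of the map ("uniform embeddedness") while specialized occupations
drift to the periphery.  Unreported categories sit on an outer ring.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
from matplotlib.patches import FancyArrowPatch, Wedge

from .builder import LivelihoodNetwork, prune_links
from .categories import CategorySet

GRAPH_FORMATS = ("graphml", "gml", "dot", "edgelist")


@dataclass(frozen=True)
class LayoutResult:
    """Node coordinates plus the seed and algorithm that produced them."""

    positions: Mapping[str, tuple[float, float]]
    seed: int
    algorithm: str = "fruchterman_reingold"


@dataclass(frozen=True)
class RenderStyle:
    """Visual-encoding knobs; linear mappings keep encodings monotone."""

    max_node_radius: float = 0.12
    edge_width_scale: float = 6.0  # width = weight * scale (linear)
    threshold: float = 0.05
    draw_empty_nodes: bool = False
    shaded_color: str = "#2b5d8a"
    unshaded_color: str = "#d9e4ee"
    figsize: tuple[float, float] = (8.0, 8.0)


@dataclass(frozen=True)
class RenderSpec:
    """What was drawn: per-node radius and pie fraction, per-edge width.

    Returned alongside the written file so encodings are testable without
    parsing the SVG.
    """

    node_radius: Mapping[str, float]
    pie_fraction: Mapping[str, float]
    edge_width: Mapping[tuple[str, str], float]
    out_path: Path


def layout_landscape(
    network: LivelihoodNetwork, seed: int = 0, threshold: float = 0.05
) -> LayoutResult:
    """Seeded spring-embedded layout on the pruned weighted graph.

    Links below ``threshold`` exert no layout force (the maps are drawn from
    the pruned network).  Categories with no surviving links are placed
    deterministically on a peripheral ring, in category-list order.
    """
    if not network.normalized:
        raise ValueError("layout requires a normalized network")
    pruned = (
        prune_links(network, threshold)
        if network.prune_threshold is None or network.prune_threshold < threshold
        else network
    )
    g = nx.DiGraph()
    for (o, d), w in (pruned.weights or {}).items():
        g.add_edge(o, d, weight=w)
    connected = list(g.nodes)
    positions: dict[str, tuple[float, float]] = {}
    if connected:
        pos = nx.spring_layout(g, seed=seed, weight="weight")
        positions.update({n: (float(p[0]), float(p[1])) for n, p in pos.items()})
    ring_radius = 1.4 * max(
        (math.hypot(*p) for p in positions.values()), default=1.0
    )
    isolates = [c for c in network.categories if c not in positions]
    for i, cat in enumerate(isolates):
        angle = 2.0 * math.pi * i / max(len(isolates), 1)
        positions[cat] = (
            ring_radius * math.cos(angle),
            ring_radius * math.sin(angle),
        )
    return LayoutResult(positions=positions, seed=seed)


def render_landscape(
    network: LivelihoodNetwork,
    layout: LayoutResult,
    out_path: str | Path,
    style: RenderStyle = RenderStyle(),
) -> RenderSpec:
    """Write the landscape map (SVG reference format) and report encodings.

    Node AREA is proportional to primary + secondary counters (so radius
    goes as the square root); the shaded pie wedge covers the primary
    fraction; arrow width is linear in link weight; links below the style
    threshold are omitted.
    """
    if not network.normalized:
        raise ValueError("render requires a normalized network")
    missing = [c for c in network.categories if c not in layout.positions]
    if missing:
        raise ValueError(f"layout lacks positions for {missing}")
    totals = {c: network.total(c) for c in network.categories}
    max_total = max(totals.values()) or 1
    node_radius = {
        c: style.max_node_radius * math.sqrt(t / max_total)
        for c, t in totals.items()
        if t > 0 or style.draw_empty_nodes
    }
    pie_fraction = {
        c: (network.primary[c] / totals[c]) if totals[c] else 0.0
        for c in node_radius
    }
    edge_width = {
        (o, d): w * style.edge_width_scale
        for (o, d), w in (network.weights or {}).items()
        if w >= style.threshold
    }

    fig, ax = plt.subplots(figsize=style.figsize)
    ax.set_aspect("equal")
    ax.axis("off")
    span = 1.0
    for c in node_radius:
        x, y = layout.positions[c]
        span = max(span, abs(x) + 0.3, abs(y) + 0.3)
    ax.set_xlim(-span, span)
    ax.set_ylim(-span, span)

    for (o, d), width in sorted(edge_width.items()):
        ax.add_patch(
            FancyArrowPatch(
                layout.positions[o],
                layout.positions[d],
                arrowstyle="-|>",
                mutation_scale=12,
                linewidth=width,
                color="#777777",
                alpha=0.8,
                shrinkA=12,
                shrinkB=12,
                zorder=1,
            )
        )
    for c, radius in node_radius.items():
        x, y = layout.positions[c]
        frac = pie_fraction[c]
        r = max(radius, 0.015)
        ax.add_patch(
            Wedge((x, y), r, 90.0, 90.0 + 360.0 * frac,
                  facecolor=style.shaded_color, edgecolor="black",
                  linewidth=0.6, zorder=2)
        )
        if frac < 1.0:
            ax.add_patch(
                Wedge((x, y), r, 90.0 + 360.0 * frac, 450.0,
                      facecolor=style.unshaded_color, edgecolor="black",
                      linewidth=0.6, zorder=2)
            )
        ax.text(x, y - r - 0.04, c, ha="center", va="top", fontsize=8, zorder=3)

    ax.set_title(
        f"Livelihood landscape — {network.provenance or 'selection'} "
        f"(n_hh={network.n_hh}, threshold={style.threshold})",
        fontsize=10,
    )
    out_path = Path(out_path)
    fig.savefig(out_path, format=out_path.suffix.lstrip(".") or "svg",
                bbox_inches="tight", metadata={"Date": None})
    plt.close(fig)
    return RenderSpec(
        node_radius=node_radius,
        pie_fraction=pie_fraction,
        edge_width=edge_width,
        out_path=out_path,
    )


def export_graph(
    network: LivelihoodNetwork, path: str | Path, format: str | None = None
) -> Path:
    """Serialize to GraphML, GML, DOT or an edge-list CSV.

    GraphML is lossless for node counters, edge counts/weights and state
    flags and round-trips through :func:`import_graphml`.  The edge list has
    columns ``origin,destination,count,weight``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        fmt = "edgelist"
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; expected {GRAPH_FORMATS}")
    g = network.to_networkx()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gml":
        nx.write_gml(g, path)
    elif fmt == "dot":
        _write_dot(network, path)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["origin", "destination", "count", "weight"])
            for (o, d), count in sorted(network.links.items()):
                weight = (
                    network.weights[(o, d)] if network.weights is not None else ""
                )
                writer.writerow([o, d, count, weight])
    return path


def _write_dot(network: LivelihoodNetwork, path: Path) -> None:
    # minimal hand-rolled DOT writer: digraph, penwidth from weight
    lines = ["digraph livelihood_landscape {"]
    for c in network.categories:
        lines.append(
            f'  "{c}" [primary={network.primary[c]} secondary={network.secondary[c]}];'
        )
    for (o, d), count in sorted(network.links.items()):
        attrs = f"count={count}"
        if network.weights is not None:
            attrs += f' weight="{network.weights[(o, d)]:.6f}"'
        lines.append(f'  "{o}" -> "{d}" [{attrs}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def import_graphml(path: str | Path) -> LivelihoodNetwork:
    """Rebuild a :class:`LivelihoodNetwork` from a GraphML export."""
    g = nx.read_graphml(path)
    categories = CategorySet(tuple(g.nodes))
    primary = {n: int(g.nodes[n]["primary"]) for n in g.nodes}
    secondary = {n: int(g.nodes[n]["secondary"]) for n in g.nodes}
    links = {(o, d): int(a["count"]) for o, d, a in g.edges(data=True)}
    normalized = bool(g.graph.get("normalized", False))
    weights = (
        {(o, d): float(a["weight"]) for o, d, a in g.edges(data=True)}
        if normalized
        else None
    )
    prune_threshold = g.graph.get("prune_threshold")
    return LivelihoodNetwork(
        categories=categories,
        primary=primary,
        secondary=secondary,
        links=links,
        weights=weights,
        normalized=normalized,
        prune_threshold=(
            float(prune_threshold) if prune_threshold is not None else None
        ),
        binary=bool(g.graph.get("binary", False)),
        provenance=str(g.graph.get("provenance", "")),
        n_hh=int(g.graph.get("n_hh", 0)),
    )
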