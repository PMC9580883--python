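"""Visual styling, cell-template layout, and standard graph file export.

The visual channels mirror the network's annotation dimensions:

* edge width  ∝ prediction probability (thicker = more probable);
* edge color  = interaction type (PCPI/DPI blue, causal up green, causal
  down red, other gray, glycoside→aglycone dark-green dashed);
* ligand nodes are circles: opacity ∝ log P (more lipophilic = more opaque),
  size from GI absorption (high = large), border color binned from the
  bioavailability score (red/orange/green), fill from ligand class;
* protein nodes are pink squares with label color by function (oncogene red,
  tumor suppressor green, other black).

Nodes are placed inside named compartment rectangles of an abstract cell
template (extracellular, plasma membrane, cytoplasm, nucleus, mitochondrion,
other) on a jittered grid, deterministically for a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import LayoutError, StyleError
from .network import AnnotatedNetwork

__all__ = [
    "StyleMap",
    "CompartmentGeometry",
    "DEFAULT_GEOMETRY",
    "compute_style",
    "layout_compartments",
    "write_graph",
    "read_graphml",
    "write_legend",
    "plot_debug",
]

# matplotlib tab10 hex values; cycled over ligand classes sorted alphabetically
_CLASS_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


@dataclass(frozen=True)
class StyleMap:
    """Visual-channel assignments; all defaults overridable."""

    edge_width_range: tuple[float, float] = (1.0, 8.0)
    edge_colors: dict = field(
        default_factory=lambda: {
            "PCPI": "#1f77b4",
            "DPI": "#1f77b4",
            "PPI-up": "#2ca02c",
            "PPI-down": "#d62728",
            "PPI-other": "#7f7f7f",
            "glycoside-aglycone": "#006400",
        }
    )
    dashed_edge_types: tuple[str, ...] = ("glycoside-aglycone",)
    node_shapes: dict = field(
        default_factory=lambda: {"ligand": "circle", "protein": "square"}
    )
    node_opacity_range: tuple[float, float] = (0.3, 1.0)
    node_size_map: dict = field(default_factory=lambda: {"high": 40.0, "low": 20.0})
    bioavailability_bins: tuple[float, float] = (0.3, 0.7)  # low/medium, medium/high
    border_colors: tuple[str, str, str] = ("#d62728", "#ff7f0e", "#2ca02c")
    protein_fill: str = "#ffc0cb"
    label_colors: dict = field(
        default_factory=lambda: {
            "oncogene": "#d62728",
            "tumor suppressor": "#2ca02c",
            "other": "#000000",
        }
    )


@dataclass(frozen=True)
class CompartmentGeometry:
    """Named rectangles (x, y, width, height) of the cell template."""

    rectangles: dict

    def rect(self, compartment: str) -> tuple[float, float, float, float]:
        try:
            return self.rectangles[compartment]
        except KeyError:
            raise LayoutError(f"no rectangle for compartment {compartment!r}") from None


DEFAULT_GEOMETRY = CompartmentGeometry(
    rectangles={
        "extracellular": (0.0, 0.0, 1000.0, 130.0),
        "plasma membrane": (0.0, 140.0, 1000.0, 120.0),
        "cytoplasm": (0.0, 270.0, 560.0, 400.0),
        "nucleus": (580.0, 270.0, 400.0, 190.0),
        "mitochondrion": (580.0, 480.0, 400.0, 190.0),
        "other": (0.0, 690.0, 1000.0, 100.0),
    }
)


def _linear(value: float, lo: float, hi: float, out_lo: float, out_hi: float) -> float:
    if hi == lo:
        return out_hi
    frac = (value - lo) / (hi - lo)
    return out_lo + frac * (out_hi - out_lo)


def _bioavailability_color(score: float, style: StyleMap) -> str:
    lo, hi = style.bioavailability_bins
    if score < lo:
        return style.border_colors[0]
    if score < hi:
        return style.border_colors[1]
    return style.border_colors[2]


def compute_style(network: AnnotatedNetwork, style: StyleMap | None = None) -> AnnotatedNetwork:
    """Attach per-node/per-edge visual attributes; monotone numeric maps.

    Probability p maps onto edge width as min + p·(max − min). log P maps
    linearly from the network's observed [min, max] onto the opacity range.
    Missing pharmacokinetic values take the channel minimum and set
    ``pk_missing``.
    """
    style = style or StyleMap()
    g = network.graph

    for u, v, d in g.edges(data=True):
        edge_type = d.get("edge_type")
        if edge_type not in style.edge_colors:
            raise StyleError(f"no color defined for edge type {edge_type!r}")
        w_lo, w_hi = style.edge_width_range
        p = d.get("probability")
        d["width"] = w_lo + float(p) * (w_hi - w_lo) if p is not None else w_lo
        d["color"] = style.edge_colors[edge_type]
        d["line_style"] = "dashed" if edge_type in style.dashed_edge_types else "solid"

    classes = sorted(
        {
            d.get("ligand_class", "")
            for _, d in g.nodes(data=True)
            if d.get("node_kind") == "ligand"
        }
    )
    class_fill = {c: _CLASS_PALETTE[i % len(_CLASS_PALETTE)] for i, c in enumerate(classes)}

    logps = [
        d["logp"]
        for _, d in g.nodes(data=True)
        if d.get("node_kind") == "ligand" and d.get("logp") is not None
    ]
    logp_lo, logp_hi = (min(logps), max(logps)) if logps else (0.0, 0.0)
    o_lo, o_hi = style.node_opacity_range

    for n, d in g.nodes(data=True):
        kind = d.get("node_kind")
        d["shape"] = style.node_shapes[kind]
        if kind == "protein":
            d["fill"] = style.protein_fill
            d["label_color"] = style.label_colors.get(d.get("function", "other"))
            continue
        d["fill"] = class_fill[d.get("ligand_class", "")]
        missing = False
        if d.get("logp") is None:
            d["opacity"], missing = o_lo, True
        else:
            d["opacity"] = _linear(d["logp"], logp_lo, logp_hi, o_lo, o_hi)
        if d.get("gi_absorption") is None:
            d["size"], missing = min(style.node_size_map.values()), True
        else:
            d["size"] = style.node_size_map[d["gi_absorption"]]
        if d.get("bioavailability") is None:
            d["border_color"], missing = style.border_colors[0], True
        else:
            d["border_color"] = _bioavailability_color(d["bioavailability"], style)
        d["pk_missing"] = missing
    return network


def layout_compartments(
    network: AnnotatedNetwork,
    geometry: CompartmentGeometry | None = None,
    seed: int = 0,
    margin_frac: float = 0.1,
    jitter_frac: float = 0.2,
) -> dict[str, tuple[float, float]]:
    """Place each node inside its compartment's rectangle on a jittered grid.

    Deterministic for a given seed. Within one compartment the grid pitch
    bounds the minimum pairwise separation at (1 − 2·jitter_frac) of the
    smaller cell dimension. A lone node sits at the rectangle center.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    g = network.graph

    by_compartment: dict[str, list[str]] = {}
    for n in sorted(g.nodes):
        compartment = g.nodes[n].get("compartment", "other")
        if compartment not in geometry.rectangles:
            raise LayoutError(f"node {n!r}: no rectangle for compartment {compartment!r}")
        by_compartment.setdefault(compartment, []).append(n)

    coords: dict[str, tuple[float, float]] = {}
    for compartment in sorted(by_compartment):
        nodes = by_compartment[compartment]
        x, y, w, h = geometry.rect(compartment)
        if len(nodes) == 1:
            coords[nodes[0]] = (x + w / 2.0, y + h / 2.0)
            continue
        ncol = math.ceil(math.sqrt(len(nodes)))
        nrow = math.ceil(len(nodes) / ncol)
        inner_x, inner_y = x + margin_frac * w, y + margin_frac * h
        inner_w, inner_h = w * (1 - 2 * margin_frac), h * (1 - 2 * margin_frac)
        cell_w, cell_h = inner_w / ncol, inner_h / nrow
        for i, node in enumerate(nodes):
            row, col = divmod(i, ncol)
            cx = inner_x + (col + 0.5) * cell_w
            cy = inner_y + (row + 0.5) * cell_h
            jx = float(rng.uniform(-jitter_frac, jitter_frac)) * cell_w
            jy = float(rng.uniform(-jitter_frac, jitter_frac)) * cell_h
            coords[node] = (cx + jx, cy + jy)
    return coords


def _exportable(network: AnnotatedNetwork, coordinates: dict | None) -> nx.MultiDiGraph:
    """Copy with None attributes dropped and coordinates attached (GraphML-safe)."""
    g = nx.MultiDiGraph()
    g.graph.update(network.graph.graph)
    for n, d in network.graph.nodes(data=True):
        attrs = {k: v for k, v in d.items() if v is not None}
        if coordinates is not None:
            attrs["x"], attrs["y"] = coordinates[n]
        g.add_node(n, **attrs)
    for u, v, k, d in network.graph.edges(keys=True, data=True):
        g.add_edge(u, v, key=k, **{kk: vv for kk, vv in d.items() if vv is not None})
    return g


def write_graph(
    network: AnnotatedNetwork,
    coordinates: dict | None,
    path,
    fmt: str = "graphml",
) -> None:
    """Serialize the styled network: graphml | cytoscape-json | csv.

    ``csv`` writes ``<path>.nodes.csv`` and ``<path>.edges.csv``. All node,
    edge, and coordinate attributes are preserved; re-reading a GraphML file
    reproduces the attribute multisets exactly.
    """
    g = _exportable(network, coordinates)
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt in ("cytoscape-json", "json"):
        payload = nx.cytoscape_data(g)
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
    elif fmt == "csv":
        node_rows = [{"node_id": n, **d} for n, d in g.nodes(data=True)]
        edge_rows = [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)]
        pd.DataFrame(node_rows).to_csv(path + ".nodes.csv", index=False)
        pd.DataFrame(edge_rows).to_csv(path + ".edges.csv", index=False)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_graphml(path) -> AnnotatedNetwork:
    return AnnotatedNetwork(nx.read_graphml(path, force_multigraph=True))


def write_legend(style: StyleMap, path) -> None:
    """Human-readable description of every visual channel."""
    lines = [
        "Visual legend",
        "=============",
        f"edge width: probability p -> {style.edge_width_range[0]} + "
        f"p * {style.edge_width_range[1] - style.edge_width_range[0]}",
        "edge colors:",
    ]
    lines += [f"  {t}: {c}" for t, c in style.edge_colors.items()]
    lines += [
        f"dashed edge types: {', '.join(style.dashed_edge_types)}",
        f"node shapes: {style.node_shapes}",
        f"ligand opacity: log P mapped linearly onto {style.node_opacity_range}"
        " (lower log P = more transparent)",
        f"ligand size: GI absorption {style.node_size_map}",
        f"ligand border: bioavailability bins {style.bioavailability_bins} -> "
        f"{style.border_colors} (low/medium/high)",
        f"protein fill: {style.protein_fill}",
        f"protein label color by function: {style.label_colors}",
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")


def plot_debug(
    network: AnnotatedNetwork,
    coordinates: dict,
    path,
    geometry: CompartmentGeometry | None = None,
) -> None:
    """Minimal static rendering of the laid-out network (debugging aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    geometry = geometry or DEFAULT_GEOMETRY
    fig, ax = plt.subplots(figsize=(10, 8))
    for name, (x, y, w, h) in geometry.rectangles.items():
        ax.add_patch(Rectangle((x, y), w, h, fill=False, edgecolor="gray"))
        ax.text(x + 4, y + 12, name, fontsize=8, color="gray")
    for u, v, d in network.graph.edges(data=True):
        (x1, y1), (x2, y2) = coordinates[u], coordinates[v]
        ax.plot(
            [x1, x2],
            [y1, y2],
            color=d.get("color", "#999999"),
            linewidth=0.5 + 0.2 * d.get("width", 1.0),
            linestyle="--" if d.get("line_style") == "dashed" else "-",
            alpha=0.6,
            zorder=1,
        )
    for n, d in network.graph.nodes(data=True):
        x, y = coordinates[n]
        ax.scatter(
            [x],
            [y],
            s=d.get("size", 25.0),
            c=d.get("fill", "#cccccc"),
            alpha=d.get("opacity", 1.0),
            marker="o" if d.get("shape") == "circle" else "s",
            edgecolors=d.get("border_color", "black"),
            zorder=2,
        )
    ax.set_xlim(-20, 1020)
    ax.set_ylim(810, -20)
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
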