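"""Assembly and cleaning of the typed, directed disease interaction network.

Nodes are ligands (phytochemicals and control drugs) and proteins. Edge types:

* ``PCPI`` / ``DPI`` — predicted ligand→protein interaction with probability
  (``DPI`` when the ligand is a control drug);
* ``PPI-up`` / ``PPI-down`` / ``PPI-other`` — directed causal protein edges;
* ``glycoside-aglycone`` — parent glycoside → hydrolysis product.

The join clause is the disease target set: protein nodes exist only for
disease targets and causal edges are kept only when both endpoints are in
that set, so no intermediate proteins are pulled in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import AssemblyError
from .ligands import LigandRegistry
from .tables import PCPIRecord, PPIRecord

logger = logging.getLogger(__name__)

__all__ = ["AnnotatedNetwork", "assemble_network", "clean", "network_summary",
           "write_network_csv", "read_network_csv"]

EDGE_TYPES = ("PCPI", "DPI", "PPI-up", "PPI-down", "PPI-other", "glycoside-aglycone")

_EFFECT_TO_TYPE = {
    "up-regulates": "PPI-up",
    "down-regulates": "PPI-down",
    "other": "PPI-other",
}


@dataclass
class AnnotatedNetwork:
    """A typed multigraph plus whatever annotations stages have attached.

    Thin wrapper over :class:`networkx.MultiDiGraph`; node attributes carry
    ``node_kind`` ("ligand"/"protein") and any payload (class, role,
    compartment, PK, function), edge attributes carry ``edge_type`` and the
    optional ``probability`` / ``effect_provenance``.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("node_kind") == kind]

    def edges_of_type(self, edge_type: str):
        return [
            (u, v, k, d)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if d.get("edge_type") == edge_type
        ]

    def copy(self) -> "AnnotatedNetwork":
        return AnnotatedNetwork(self.graph.copy())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def assemble_network(
    disease_pcpis: list[PCPIRecord],
    ppis: list[PPIRecord],
    relations: list[tuple[str, str]],
    registry: LigandRegistry,
    control_ids: set[str] | None = None,
) -> AnnotatedNetwork:
    """Join disease-filtered ligand→protein records with causal protein edges.

    Ligand nodes are created for every ligand with at least one disease
    record and protein nodes for every disease target. Causal edges are kept
    only when both endpoints are disease proteins; glycoside→aglycone edges
    only when both ligands made it into the network. Ligand→protein edges are
    typed ``DPI`` for control drugs (``control_ids``), ``PCPI`` otherwise.
    """
    control_ids = control_ids or set()
    net = AnnotatedNetwork()
    g = net.graph

    proteins = {r.protein for r in disease_pcpis}
    ligands = {r.ligand_id for r in disease_pcpis}

    for ligand_id in sorted(ligands):
        if ligand_id not in registry:
            raise AssemblyError(f"interaction references unknown ligand {ligand_id!r}")
        rec = registry.get(ligand_id)
        g.add_node(
            ligand_id,
            node_kind="ligand",
            name=rec.name,
            ligand_class=rec.ligand_class,
            role=rec.role,
        )
    for protein in sorted(proteins):
        g.add_node(protein, node_kind="protein")

    for r in disease_pcpis:
        edge_type = "DPI" if r.ligand_id in control_ids else "PCPI"
        g.add_edge(r.ligand_id, r.protein, edge_type=edge_type, probability=r.probability)

    n_ppi_dropped = 0
    for p in ppis:
        if p.source in proteins and p.target in proteins:
            g.add_edge(
                p.source,
                p.target,
                edge_type=_EFFECT_TO_TYPE[p.effect],
                effect_provenance=p.provenance,
            )
        else:
            n_ppi_dropped += 1
    if n_ppi_dropped:
        logger.info("dropped %d causal edges outside the disease target set", n_ppi_dropped)

    for parent, child in relations:
        if parent in ligands and child in ligands:
            g.add_edge(parent, child, edge_type="glycoside-aglycone")
        else:
            logger.info("glycoside relation (%s, %s) outside network, dropped", parent, child)
    return net


def clean(network: AnnotatedNetwork) -> AnnotatedNetwork:
    """Remove self-loops and duplicate (source, target, edge_type) edges.

    Within a duplicate group the edge with the highest probability survives
    (edges without probability: first encountered). Idempotent.
    """
    out = AnnotatedNetwork(nx.MultiDiGraph())
    out.graph.add_nodes_from(network.graph.nodes(data=True))
    out.graph.graph.update(network.graph.graph)

    best: dict[tuple[str, str, str], dict] = {}
    order: list[tuple[str, str, str]] = []
    n_loops = n_dups = 0
    for u, v, d in network.graph.edges(data=True):
        if u == v:
            n_loops += 1
            continue
        key = (u, v, d.get("edge_type"))
        if key not in best:
            best[key] = d
            order.append(key)
        else:
            n_dups += 1
            old_p, new_p = best[key].get("probability"), d.get("probability")
            if old_p is not None and new_p is not None and new_p > old_p:
                best[key] = d
    for key in order:
        u, v, _ = key
        out.graph.add_edge(u, v, **best[key])
    if n_loops or n_dups:
        logger.info("clean: removed %d self-loops, %d duplicate edges", n_loops, n_dups)
    return out


def network_summary(network: AnnotatedNetwork) -> pd.DataFrame:
    """Counts of nodes by kind/class and edges by type; partitions are exact."""
    rows = []
    nodes = network.graph.nodes(data=True)
    for kind in ("ligand", "protein"):
        members = [d for _, d in nodes if d.get("node_kind") == kind]
        rows.append({"category": "node_kind", "value": kind, "count": len(members)})
    classes: dict[str, int] = {}
    for _, d in nodes:
        if d.get("node_kind") == "ligand":
            classes[d.get("ligand_class", "")] = classes.get(d.get("ligand_class", ""), 0) + 1
    for cls in sorted(classes):
        rows.append({"category": "ligand_class", "value": cls, "count": classes[cls]})
    for edge_type in EDGE_TYPES:
        n = sum(1 for _, _, d in network.graph.edges(data=True) if d.get("edge_type") == edge_type)
        rows.append({"category": "edge_type", "value": edge_type, "count": n})
    rows.append({"category": "total", "value": "nodes", "count": network.n_nodes})
    rows.append({"category": "total", "value": "edges", "count": network.n_edges})
    return pd.DataFrame(rows, columns=["category", "value", "count"])


def write_network_csv(network: AnnotatedNetwork, nodes_path, edges_path) -> None:
    """Lossless node/edge table export (attributes become columns)."""
    node_rows = [{"node_id": n, **d} for n, d in network.graph.nodes(data=True)]
    edge_rows = [
        {"source": u, "target": v, **d} for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(node_rows).to_csv(nodes_path, index=False)
    pd.DataFrame(edge_rows).to_csv(edges_path, index=False)


def read_network_csv(nodes_path, edges_path) -> AnnotatedNetwork:
    net = AnnotatedNetwork()
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    for _, row in nodes.iterrows():
        attrs = {k: v for k, v in row.items() if k != "node_id" and pd.notna(v)}
        net.graph.add_node(str(row["node_id"]), **attrs)
    for _, row in edges.iterrows():
        attrs = {
            k: v for k, v in row.items() if k not in ("source", "target") and pd.notna(v)
        }
        net.graph.add_edge(str(row["source"]), str(row["target"]), **attrs)
    return net
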