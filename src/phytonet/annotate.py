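"""Node annotation: subcellular locations, pharmacokinetics, protein function.

Protein compartments come from a primary lookup (a spatial-proteomics style
protein→compartment table), falling back to a second table (curated
annotations) and finally to "other". Ligands inherit a location from their
own targets through a fixed priority rule — nucleus, then mitochondrion,
then plasma membrane, then cytoplasm — reflecting where an interaction would
matter most; when no target lies in any of those four tiers the plurality
compartment among targets wins (alphabetical tie-break).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import AnnotationError
from .network import AnnotatedNetwork
from .tables import PKAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentAssignment",
    "normalize_compartment",
    "read_location_table",
    "read_function_table",
    "assign_protein_locations",
    "assign_ligand_location",
    "assign_ligand_locations",
    "annotate_pharmacokinetics",
    "annotate_protein_function",
]

PRIORITY_TIERS = ("nucleus", "mitochondrion", "plasma membrane", "cytoplasm")

# controlled vocabulary; everything else passes through lower-cased
_COMPARTMENT_SYNONYMS = {
    "cytosol": "cytoplasm",
    "cytoplasmic": "cytoplasm",
    "pm": "plasma membrane",
    "cell membrane": "plasma membrane",
    "membrane": "plasma membrane",
    "mitochondria": "mitochondrion",
    "mitochondrial": "mitochondrion",
    "nuclear": "nucleus",
    "secreted": "extracellular",
    "extracellular space": "extracellular",
    "extracellular region": "extracellular",
}


@dataclass(frozen=True)
class CompartmentAssignment:
    node_id: str
    compartment: str
    provenance: str  # primary-table | fallback-table | ligand-priority-rule | plurality-fallback


def normalize_compartment(raw: str) -> str:
    low = str(raw).strip().lower()
    return _COMPARTMENT_SYNONYMS.get(low, low)


def read_location_table(path) -> dict[str, str]:
    """CSV protein,compartment → normalized lookup; first listed value wins."""
    frame = pd.read_csv(path, encoding="utf-8")
    lookup: dict[str, str] = {}
    for _, row in frame.iterrows():
        protein = str(row["protein"]).strip().upper()
        if protein in lookup:
            logger.info("location table %s: extra compartment for %s ignored", path, protein)
            continue
        # multi-compartment cells list alternatives separated by ';'
        first = str(row["compartment"]).split(";")[0]
        lookup[protein] = normalize_compartment(first)
    return lookup


def read_function_table(path) -> dict[str, str]:
    """CSV protein,function with values oncogene / tumor suppressor / other."""
    frame = pd.read_csv(path, encoding="utf-8")
    return {
        str(row["protein"]).strip().upper(): str(row["function"]).strip().lower()
        for _, row in frame.iterrows()
    }


def assign_protein_locations(
    network: AnnotatedNetwork,
    primary_map: dict[str, str],
    fallback_map: dict[str, str] | None = None,
) -> AnnotatedNetwork:
    """Attach a compartment to every protein node (primary, fallback, "other")."""
    fallback_map = fallback_map or {}
    for node in network.nodes_of_kind("protein"):
        if node in primary_map:
            compartment, provenance = primary_map[node], "primary-table"
        elif node in fallback_map:
            compartment, provenance = fallback_map[node], "fallback-table"
        else:
            compartment, provenance = "other", "fallback-table"
            logger.warning("protein %s in neither location table; placed in 'other'", node)
        network.graph.nodes[node]["compartment"] = compartment
        network.graph.nodes[node]["compartment_provenance"] = provenance
    return network


def assign_ligand_location(
    ligand_node: str, target_compartments: list[str]
) -> CompartmentAssignment:
    """Place a ligand by its targets: four priority tiers, then plurality.

    Any target in the nucleus pins the ligand to the nucleus, else
    mitochondrion, else plasma membrane, else cytoplasm; otherwise the most
    common target compartment wins, ties broken alphabetically.
    """
    if not target_compartments:
        raise AnnotationError(f"ligand {ligand_node!r} has no targets to locate it")
    compartments = [normalize_compartment(c) for c in target_compartments]
    for tier in PRIORITY_TIERS:
        if tier in compartments:
            return CompartmentAssignment(ligand_node, tier, "ligand-priority-rule")
    counts = Counter(compartments)
    top = max(counts.values())
    winner = sorted(c for c, n in counts.items() if n == top)[0]
    return CompartmentAssignment(ligand_node, winner, "plurality-fallback")


def assign_ligand_locations(network: AnnotatedNetwork) -> AnnotatedNetwork:
    """Apply the priority rule to every ligand, from its own PCPI/DPI targets."""
    g = network.graph
    for ligand in network.nodes_of_kind("ligand"):
        targets = [
            v
            for _, v, d in g.out_edges(ligand, data=True)
            if d.get("edge_type") in ("PCPI", "DPI")
        ]
        compartments = [g.nodes[t].get("compartment", "other") for t in targets]
        assignment = assign_ligand_location(ligand, compartments)
        g.nodes[ligand]["compartment"] = assignment.compartment
        g.nodes[ligand]["compartment_provenance"] = assignment.provenance
    return network


def annotate_pharmacokinetics(
    network: AnnotatedNetwork, pk: list[PKAnnotation]
) -> AnnotatedNetwork:
    """Attach bioavailability, GI absorption and log P to ligand nodes."""
    by_id = {p.ligand_id: p for p in pk}
    for ligand in network.nodes_of_kind("ligand"):
        node = network.graph.nodes[ligand]
        record = by_id.get(ligand)
        if record is None:
            logger.warning("ligand %s has no pharmacokinetic record", ligand)
            node.update(bioavailability=None, gi_absorption=None, logp=None)
        else:
            node.update(
                bioavailability=record.bioavailability,
                gi_absorption=record.gi_absorption,
                logp=record.logp,
            )
    return network


def annotate_protein_function(
    network: AnnotatedNetwork, function_map: dict[str, str]
) -> AnnotatedNetwork:
    """Attach oncogene / tumor suppressor / other labels; unmapped → other."""
    for protein in network.nodes_of_kind("protein"):
        network.graph.nodes[protein]["function"] = function_map.get(protein, "other")
    return network
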