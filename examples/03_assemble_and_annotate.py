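"""Assemble the disease network, clean it, and attach annotations.

Causal protein edges are kept only when both endpoints are disease targets
(the join clause). Ligands inherit a compartment from their targets via the
priority rule nucleus > mitochondrion > plasma membrane > cytoplasm.
"""

from pathlib import Path

from phytonet import (
    annotate_pharmacokinetics,
    annotate_protein_function,
    assemble_network,
    assign_ligand_locations,
    assign_protein_locations,
    build_registry,
    clean,
    filter_to_pathway,
    network_summary,
    read_gmt,
)
from phytonet.annotate import read_function_table, read_location_table
from phytonet.ligands import read_ligand_table
from phytonet.tables import read_adme_table, read_ppi_table, read_target_predictions

data = Path(__file__).parent / "data"
registry = build_registry(read_ligand_table(data / "ligands_sample.csv"))

# for brevity, reuse one prediction file for two ligands
pcpis = read_target_predictions(data / "predictions_sample.csv", "quercetin")
pcpis += read_target_predictions(data / "predictions_sample.csv", "sorafenib")
disease = next(gs for gs in read_gmt(data / "pathways_sample.gmt") if gs.pathway_id == "PW0001")
overlap = set(disease.genes) & {r.protein for r in pcpis}
disease_pcpis = filter_to_pathway(pcpis, disease, overlap)

ppis = read_ppi_table(data / "ppi_sample.tsv")
net = clean(
    assemble_network(disease_pcpis, ppis, registry.relations, registry, {"sorafenib"})
)

locations = read_location_table(data / "locations_sample.csv")
assign_protein_locations(net, locations)
assign_ligand_locations(net)
annotate_pharmacokinetics(net, read_adme_table(data / "adme_sample.csv", registry=registry))
annotate_protein_function(net, read_function_table(data / "functions_sample.csv"))

print(network_summary(net).to_string(index=False))
print("\nnode annotations:")
for n, d in net.graph.nodes(data=True):
    extra = f" logP={d['logp']}" if d.get("logp") is not None else ""
    print(f"  {n:10s} {d['node_kind']:7s} {d.get('compartment', '?'):15s}{extra}")
# Sorafenib's edges are typed DPI (drug control); quercetin's are PCPIs.
# The chemical row in the causal table was dropped on read.
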