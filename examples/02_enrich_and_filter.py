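"""Ingest reverse-screening predictions and filter them to a disease pathway.

Zero-probability rows mean "no evidence" and are dropped on read. The
remaining targets are tested for pathway over-representation (hypergeometric
upper tail, Benjamini-Hochberg adjusted); the chosen pathway's overlap with
the predicted targets then restricts the interaction list.
"""

from pathlib import Path

from phytonet import filter_to_pathway, overrepresentation_test, read_gmt
from phytonet.tables import read_target_predictions

data = Path(__file__).parent / "data"
pcpis = read_target_predictions(data / "predictions_sample.csv", ligand_id="quercetin")
print(f"{len(pcpis)} predictions with probability > 0 (zero rows dropped):")
for r in pcpis:
    print(f"  quercetin -> {r.protein:8s} P = {r.probability}")

gene_sets = read_gmt(data / "pathways_sample.gmt")
targets = {r.protein for r in pcpis}
# alpha=1.0 returns every tested pathway so the ranking is visible; with a
# 13-gene toy background three targets cannot reach 0.05 significance
results = overrepresentation_test(targets, gene_sets, alpha=1.0)
print("\npathways ranked by adjusted p (toy background of "
      f"{len(set().union(*(gs.genes for gs in gene_sets)))} genes):")
for res in results:
    print(
        f"  {res.pathway_id}  p = {res.p_value:.3g}  adj = {res.adjusted_p:.3g}"
        f"  overlap = {sorted(res.overlap)}"
    )

disease = next(gs for gs in gene_sets if gs.pathway_id == "PW0001")
overlap = set(disease.genes) & targets
kept = filter_to_pathway(pcpis, disease, overlap)
print(f"\n{len(kept)} of {len(pcpis)} interactions survive the {disease.pathway_id} filter")
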