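"""Compile a small ligand list: canonicalize, deduplicate, hydrolyze glycosides.

Salicin is a phenolic glycoside; hydrolysis releases saligenin, which is
already on the list, so the product merges into the existing record and only
the parent→aglycone relation is added. Quercetin carries no sugar unit.
"""

from pathlib import Path

from phytonet import build_registry, hydrolyze_glycosides
from phytonet.ligands import read_ligand_table

table = read_ligand_table(Path(__file__).parent / "data" / "ligands_sample.csv")
registry = build_registry(table)

print(f"{len(table)} input rows -> {len(registry)} registry records\n")
for rec in registry:
    parent = f"  (from {rec.parent_id})" if rec.parent_id else ""
    print(f"  {rec.ligand_id:12s} {rec.ligand_class:20s} {rec.smiles}{parent}")

print("\nglycoside -> aglycone relations:", registry.relations)

salicin = registry.get("salicin")
result = hydrolyze_glycosides(salicin)
print(f"\nhydrolysis of salicin cleaved {result.bonds_cleaved} glycosidic bond(s):")
for smiles, kind in result.products:
    print(f"  {kind:9s} {smiles}")
# The sugar fragment (glucose) is reported here but never registered as a
# ligand; only the aglycone enters the downstream network.
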