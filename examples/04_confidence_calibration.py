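"""Calibrate interaction confidence against docking energies.

Probability-1 predictions are interactions already recorded in a bioactivity
database; the most negative docking energy among them is the soft cutoff and
the upper bound of their mean + 3 SD band is the hard cutoff. Probability
regions are then derived from the low and medium docking groups.
"""

from pathlib import Path

from phytonet import calibrate, classify_interactions
from phytonet.tables import read_docking_table

dockings = read_docking_table(Path(__file__).parent / "data" / "docking_sample.csv")
model = calibrate(dockings)

print("calibrated confidence model:")
print(model.to_yaml())

print("classified interactions:")
for c in classify_interactions(dockings, model):
    d = c.docking
    print(
        f"  {d.ligand_id:10s} -> {d.protein:6s} E = {d.energy:5.1f} kcal/mol "
        f"P = {d.probability:<5g} docking: {c.docking_confidence:6s} "
        f"probability: {c.probability_confidence}"
    )
# An edge survives into the simplified high-confidence network when its
# docking confidence is high OR its prediction probability equals 1.
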