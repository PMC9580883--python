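"""Synthetic, internally consistent input bundles with known ground truth.

The generator emulates every external table the pipeline consumes — ligand
lists, per-ligand reverse-screening predictions, causal protein interactions,
pathway gene sets, ADME properties, location/function lookups, and docking
energies — for a toy plant-vs-disease study. Glycosides are constructed by
attaching a glucose unit to real aglycone scaffolds, so the hydrolysis ground
truth is exact by construction. The bundle tests plumbing and math, not
science: probabilities, energies and gene assignments are draws from simple
distributions, with no chemical or biological realism intended.

All randomness flows through one seeded generator; the same spec yields a
byte-identical bundle. The accompanying ``manifest.json`` records expected
aglycone structures, record counts at every stage, post-clean network
composition, and the calibration values implied by the drawn docking table —
all derived by set arithmetic over the constructed inputs, independently of
the pipeline stages themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import FixtureSpecError
from .ligands import build_registry, canonicalize_structure

__all__ = ["FixtureSpec", "generate_fixture_bundle", "AGLYCONE_SCAFFOLDS"]

# (name, SMILES, class) — each scaffold carries a free hydroxyl for glycosylation
AGLYCONE_SCAFFOLDS = (
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "flavonoid"),
    ("luteolin", "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "flavonoid"),
    ("kaempferol", "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "flavonoid"),
    ("apigenin", "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "flavonoid"),
    ("saligenin", "OCc1ccccc1O", "phenolic"),
    ("caffeic acid", "O=C(O)/C=C/c1ccc(O)c(O)c1", "phenolic acid"),
    ("ferulic acid", "COc1cc(/C=C/C(=O)O)ccc1O", "phenolic acid"),
    ("gallic acid", "O=C(O)c1cc(O)c(O)c(O)c1", "phenolic acid"),
    ("protocatechuic acid", "O=C(O)c1ccc(O)c(O)c1", "phenolic acid"),
    ("vanillic acid", "COc1cc(C(=O)O)ccc1O", "phenolic acid"),
    ("p-coumaric acid", "O=C(O)/C=C/c1ccc(O)cc1", "phenolic acid"),
    ("syringic acid", "COc1cc(C(=O)O)cc(OC)c1O", "phenolic acid"),
    ("eugenol", "C=CCc1ccc(O)c(OC)c1", "phenolic"),
    ("thymol", "Cc1ccc(C(C)C)c(O)c1", "phenolic"),
    ("catechol", "Oc1ccccc1O", "phenolic"),
    ("guaiacol", "COc1ccccc1O", "phenolic"),
)

_CONTROLS = (
    (
        "sorafenib",
        "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1",
        "drug-control",
        "positive-control",
    ),
    (
        "alprazolam",
        "Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2",
        "drug-control",
        "negative-control",
    ),
)

_PROTEIN_POOL = (
    "EGFR", "MTOR", "CTNNB1", "GSK3B", "BRAF", "PIK3CA", "AKT1", "MAPK1",
    "MAP2K1", "MAP2K2", "TP53", "CCND1", "BCL2", "CASP3", "KRAS", "RAF1",
    "ARAF", "TGFBR2", "MYC", "CDK4", "SRC", "JUN", "FOS", "BAX", "APC",
)

_COMPARTMENTS = ("nucleus", "mitochondrion", "plasma membrane", "cytoplasm", "extracellular")

_EFFECT_STRINGS = {
    "up-regulates": "up-regulates activity",
    "down-regulates": "down-regulates quantity by destabilization",
    "other": "binds",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Size and distribution knobs for one synthetic study."""

    seed: int
    n_ligands: int = 12
    n_glycosides: int = 4
    n_proteins: int = 15
    n_pathways: int = 4
    pcpi_density: float = 0.35
    # database-known interactions (probability exactly 1) are a small
    # minority of predictions; they all classify as medium docking
    # confidence (none can beat the soft cutoff, their own minimum), so the
    # probability bands only stay ordered when they do not dominate that group
    prob1_fraction: float = 0.08
    # group means must realize their labels against the cutoffs the prob1
    # group implies (soft = sample min ~ mu - 2*sd, hard = mu + 3*sd): "high"
    # well below the soft cutoff, "medium" between the cutoffs, "low" above
    # the hard cutoff
    docking_group_params: dict = field(
        default_factory=lambda: {
            "prob1": (-8.0, 0.3),
            "high": (-9.5, 0.2),
            "medium": (-7.9, 0.1),
            "low": (-6.0, 0.3),
        }
    )

    def __post_init__(self):
        if self.n_glycosides > self.n_ligands:
            raise FixtureSpecError("n_glycosides must be <= n_ligands")
        if self.n_ligands - 1 > len(AGLYCONE_SCAFFOLDS):
            raise FixtureSpecError(
                f"at most {len(AGLYCONE_SCAFFOLDS) + 1} ligands supported"
            )
        if self.n_proteins > len(_PROTEIN_POOL):
            raise FixtureSpecError(f"at most {len(_PROTEIN_POOL)} proteins supported")
        if not 0.0 < self.pcpi_density <= 1.0:
            raise FixtureSpecError("pcpi_density must be in (0, 1]")
        if not 0.0 <= self.prob1_fraction <= 1.0:
            raise FixtureSpecError("prob1_fraction must be in [0, 1]")
        if self.n_pathways < 1:
            raise FixtureSpecError("need at least one pathway (the disease pathway)")
        for key in ("prob1", "medium", "low"):
            if key not in self.docking_group_params:
                raise FixtureSpecError(f"docking_group_params missing group {key!r}")


def _attach_glucose(smiles: str) -> str:
    """Bond a glucosyl unit to the molecule's first free hydroxyl oxygen."""
    mol = Chem.MolFromSmiles(smiles)
    target_o = None
    for atom in mol.GetAtoms():
        if (
            atom.GetAtomicNum() == 8
            and atom.GetDegree() == 1
            and atom.GetTotalNumHs() >= 1
            and atom.GetNeighbors()[0].GetAtomicNum() == 6
        ):
            target_o = atom.GetIdx()
            break
    if target_o is None:
        raise FixtureSpecError(f"no free hydroxyl to glycosylate in {smiles!r}")
    glucosyl = Chem.MolFromSmiles("C1OC(CO)C(O)C(O)C1O")  # anomeric carbon = atom 0
    combo = Chem.RWMol(Chem.CombineMols(mol, glucosyl))
    combo.AddBond(target_o, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_fixture_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write a complete input bundle + ground-truth manifest; return the manifest."""
    out = Path(out_dir)
    (out / "predictions").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # --- ligand table -----------------------------------------------------
    glycoside_scaffolds = AGLYCONE_SCAFFOLDS[: spec.n_glycosides]
    n_plain = spec.n_ligands - spec.n_glycosides
    # overlap one scaffold so a glycoside's aglycone is also listed directly
    plain_start = max(spec.n_glycosides - 1, 0) if n_plain else spec.n_glycosides
    plain_scaffolds = AGLYCONE_SCAFFOLDS[plain_start : plain_start + n_plain]

    rows = []
    glycoside_names = []
    expected_aglycones = {}
    for name, smiles, cls in glycoside_scaffolds:
        gname = f"{name} glucoside"
        rows.append(
            {
                "name": gname,
                "smiles": _attach_glucose(smiles),
                "class": f"{cls} glycoside",
                "role": "phytochemical",
            }
        )
        glycoside_names.append(gname)
        expected_aglycones[gname] = canonicalize_structure(smiles)
    for name, smiles, cls in plain_scaffolds:
        rows.append({"name": name, "smiles": smiles, "class": cls, "role": "phytochemical"})
    for name, smiles, cls, role in _CONTROLS:
        rows.append({"name": name, "smiles": smiles, "class": cls, "role": role})
    ligand_table = pd.DataFrame(rows, columns=["name", "smiles", "class", "role"])
    ligand_table.to_csv(out / "ligands.csv", index=False)

    # expected registry size by set arithmetic over canonical structures
    input_canonical = {canonicalize_structure(s) for s in ligand_table["smiles"]}
    novel_aglycones = set(expected_aglycones.values()) - input_canonical
    n_registry_expected = len(input_canonical) + len(novel_aglycones)

    # registry used ONLY to obtain ligand_ids for file naming / joins
    registry = build_registry(ligand_table)
    assert len(registry) == n_registry_expected

    # --- proteins, pathways ----------------------------------------------
    proteins = list(_PROTEIN_POOL[: spec.n_proteins])
    n_disease = max(3, round(0.7 * spec.n_proteins))
    disease_genes = set(proteins[:n_disease]) | {"PAD01", "PAD02"}  # padding genes
    extras = [f"NT{i:02d}" for i in range(1, 41)]  # never predicted for phytochemicals

    gmt_lines = [
        "PW0001\tdisease pathway\t" + "\t".join(sorted(disease_genes)),
    ]
    for i in range(2, spec.n_pathways + 1):
        members = sorted(
            set(rng.choice(extras, size=8, replace=False))
            | set(rng.choice(proteins, size=2, replace=False))
        )
        gmt_lines.append(f"PW{i:04d}\tbystander pathway {i}\t" + "\t".join(members))
    (out / "pathways.gmt").write_text("\n".join(gmt_lines) + "\n", encoding="utf-8")

    # --- per-ligand predictions -------------------------------------------
    all_genes = sorted(set(proteins) | set(extras) | disease_genes)
    uniprot = {g: f"P{10000 + i}" for i, g in enumerate(all_genes)}

    pcpis: list[tuple[str, str, float]] = []  # nonzero only
    n_zero_rows = 0
    records = list(registry)
    for li, rec in enumerate(records):
        file_rows = []
        if rec.role == "positive-control":
            k = min(5, n_disease)
            targets = [proteins[i] for i in range(k)]
            probs = [1.0] * k
        elif rec.role == "negative-control":
            targets = list(rng.choice(extras, size=3, replace=False))
            probs = [float(p) for p in rng.uniform(0.05, 0.9, size=3)]
        else:
            k = max(1, round(spec.pcpi_density * spec.n_proteins))
            targets = [str(t) for t in rng.choice(proteins, size=k, replace=False)]
            probs = [
                1.0 if rng.uniform() < spec.prob1_fraction
                else float(rng.uniform(0.05, 0.9))
                for _ in targets
            ]
        for t, p in zip(targets, probs):
            file_rows.append({"Common name": t, "Uniprot ID": uniprot[t], "Probability*": p})
            pcpis.append((rec.ligand_id, t, p))
        if li % 3 == 0:  # a zero-probability row, dropped on read
            off = extras[li % len(extras)]
            file_rows.append({"Common name": off, "Uniprot ID": uniprot[off], "Probability*": 0.0})
            n_zero_rows += 1
        pd.DataFrame(file_rows, columns=["Common name", "Uniprot ID", "Probability*"]).to_csv(
            out / "predictions" / f"{rec.ligand_id}.csv", index=False
        )

    predicted_targets = {t for _, t, _ in pcpis}
    overlap = disease_genes & predicted_targets
    disease_pcpis = [(l, t, p) for l, t, p in pcpis if t in overlap]
    network_ligands = sorted({l for l, _, _ in disease_pcpis})
    network_proteins = sorted({t for _, t, _ in disease_pcpis})
    control_ids = {
        r.ligand_id for r in records if r.role in ("positive-control", "negative-control")
    }
    n_dpi = sum(1 for l, _, _ in disease_pcpis if l in control_ids)
    n_pcpi = len(disease_pcpis) - n_dpi

    # --- causal PPI table --------------------------------------------------
    effects = ("up-regulates", "down-regulates", "other")
    ppi_pairs: list[tuple[str, str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(ppi_pairs) < 2 * spec.n_proteins and attempts < 500:
        attempts += 1
        a, b = (str(x) for x in rng.choice(proteins, size=2, replace=False))
        if (a, b) in seen_pairs:
            continue
        seen_pairs.add((a, b))
        ppi_pairs.append((a, b, effects[len(ppi_pairs) % 3]))
    ppi_rows = [
        {"ENTITYA": a, "TYPEA": "protein", "ENTITYB": b, "TYPEB": "protein",
         "EFFECT": _EFFECT_STRINGS[e], "MECHANISM": "synthetic"}
        for a, b, e in ppi_pairs
    ]
    # deliberate noise: duplicate row, self-loop, chemical row, out-of-set edge
    dup = dict(ppi_rows[0])
    ppi_rows.append(dup)
    loop_protein = network_proteins[0]
    ppi_rows.append(
        {"ENTITYA": loop_protein, "TYPEA": "protein", "ENTITYB": loop_protein,
         "TYPEB": "protein", "EFFECT": _EFFECT_STRINGS["other"], "MECHANISM": "synthetic"}
    )
    ppi_rows.append(
        {"ENTITYA": "caffeine", "TYPEA": "chemical", "ENTITYB": proteins[0],
         "TYPEB": "protein", "EFFECT": _EFFECT_STRINGS["up-regulates"], "MECHANISM": "synthetic"}
    )
    ppi_rows.append(
        {"ENTITYA": extras[0], "TYPEA": "protein", "ENTITYB": proteins[0],
         "TYPEB": "protein", "EFFECT": _EFFECT_STRINGS["down-regulates"], "MECHANISM": "synthetic"}
    )
    pd.DataFrame(
        ppi_rows, columns=["ENTITYA", "TYPEA", "ENTITYB", "TYPEB", "EFFECT", "MECHANISM"]
    ).to_csv(out / "ppi.tsv", sep="\t", index=False)

    protein_node_set = set(network_proteins)
    expected_ppi_edges = {
        (a, b, e) for a, b, e in ppi_pairs
        if a in protein_node_set and b in protein_node_set and a != b
    }

    # --- glycoside relations in the network --------------------------------
    relation_edges = [
        (p, c) for p, c in registry.relations if p in network_ligands and c in network_ligands
    ]

    # --- ADME, locations, functions ----------------------------------------
    adme_rows = []
    for rec in records:
        adme_rows.append(
            {
                "Molecule": rec.name,
                "Bioavailability Score": float(rng.choice([0.11, 0.17, 0.55, 0.56, 0.85])),
                "GI absorption": str(rng.choice(["High", "Low"])),
                "Consensus Log P": round(float(rng.uniform(-1.0, 5.0)), 2),
            }
        )
    adme_rows.append(dict(adme_rows[0]))  # identical duplicate row, collapses on read
    pd.DataFrame(
        adme_rows,
        columns=["Molecule", "Bioavailability Score", "GI absorption", "Consensus Log P"],
    ).to_csv(out / "adme.csv", index=False)

    loc_all = {p: str(rng.choice(_COMPARTMENTS)) for p in proteins}
    primary = {p: loc_all[p] for p in proteins[: max(1, round(0.7 * len(proteins)))]}
    fallback_pool = [p for p in proteins if p not in primary]
    unplaced = fallback_pool[-1] if fallback_pool else None  # exercises the "other" path
    fallback = {p: loc_all[p] for p in fallback_pool if p != unplaced}
    pd.DataFrame(
        [{"protein": p, "compartment": c} for p, c in primary.items()],
        columns=["protein", "compartment"],
    ).to_csv(out / "locations_primary.csv", index=False)
    pd.DataFrame(
        [{"protein": p, "compartment": c} for p, c in fallback.items()],
        columns=["protein", "compartment"],
    ).to_csv(out / "locations_fallback.csv", index=False)

    functions = {}
    for p in proteins:
        if p == "CTNNB1":
            functions[p] = "oncogene"
        elif p == "GSK3B":
            functions[p] = "tumor suppressor"
        else:
            functions[p] = str(
                rng.choice(["oncogene", "tumor suppressor", "other"], p=[0.3, 0.2, 0.5])
            )
    pd.DataFrame(
        [{"protein": p, "function": f} for p, f in functions.items()],
        columns=["protein", "function"],
    ).to_csv(out / "functions.csv", index=False)

    # --- docking table ------------------------------------------------------
    params = spec.docking_group_params
    dock_rows = []
    prob1_energies = []
    others = [(l, t, p) for l, t, p in disease_pcpis if p != 1.0]
    for l, t, p in disease_pcpis:
        if p == 1.0:
            e = float(rng.normal(*params["prob1"]))
            prob1_energies.append(e)
            dock_rows.append({"ligand_id": l, "protein": t, "energy": e, "probability": p})
    cycle = ("high", "medium", "low", "medium", "medium", "low")  # 1/6, 1/2, 1/3
    for i, (l, t, p) in enumerate(others):
        group = cycle[i % len(cycle)]
        if group == "high" and "high" not in params:
            group = "medium"
        e = float(rng.normal(*params[group]))
        dock_rows.append({"ligand_id": l, "protein": t, "energy": e, "probability": p})
    pd.DataFrame(dock_rows, columns=["ligand_id", "protein", "energy", "probability"]).to_csv(
        out / "docking.csv", index=False
    )

    # expected calibration by direct arithmetic over the drawn table
    expected_soft = expected_hard = None
    expected_high_thr = expected_low_thr = None
    if prob1_energies:
        arr = np.array(prob1_energies)
        expected_soft = float(arr.min())
        expected_hard = float(arr.mean() + 3.0 * arr.std(ddof=0))
        low_p = [r["probability"] for r in dock_rows if r["energy"] >= expected_hard]
        med_p = [
            r["probability"]
            for r in dock_rows
            if expected_soft <= r["energy"] < expected_hard
        ]
        if low_p and med_p:
            low_arr, med_arr = np.array(low_p), np.array(med_p)
            expected_high_thr = float(low_arr.mean() + low_arr.std(ddof=0))
            expected_low_thr = float(med_arr.mean() - med_arr.std(ddof=0))

    manifest = {
        "seed": spec.seed,
        "expected_aglycones": expected_aglycones,
        "n_registry_records": n_registry_expected,
        "n_relations": len(registry.relations),
        "n_zero_probability_rows": n_zero_rows,
        "n_complete_pcpis": len(pcpis),
        "disease_pathway_id": "PW0001",
        "n_overlap_proteins": len(overlap),
        "n_disease_pcpis": len(disease_pcpis),
        "n_ligand_nodes": len(network_ligands),
        "n_protein_nodes": len(network_proteins),
        "n_pcpi_edges": n_pcpi,
        "n_dpi_edges": n_dpi,
        "n_ppi_edges": len(expected_ppi_edges),
        "n_relation_edges": len(relation_edges),
        "n_nodes": len(network_ligands) + len(network_proteins),
        "n_edges": len(disease_pcpis) + len(expected_ppi_edges) + len(relation_edges),
        "expected_soft_cutoff": expected_soft,
        "expected_hard_cutoff": expected_hard,
        "expected_prob_high_threshold": expected_high_thr,
        "expected_prob_low_threshold": expected_low_thr,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)

    config = {
        "seed": spec.seed,
        "pathway": "PW0001",
        "alpha": 0.05,
        "exhaustive_hydrolysis": True,
        "inputs": {
            "ligands": "ligands.csv",
            "predictions_dir": "predictions",
            "ppi": "ppi.tsv",
            "gene_sets": "pathways.gmt",
            "adme": "adme.csv",
            "locations_primary": "locations_primary.csv",
            "locations_fallback": "locations_fallback.csv",
            "functions": "functions.csv",
            "docking": "docking.csv",
        },
        "confidence": {"k_hard": 3.0, "k_prob": 1.0, "ddof": 0},
    }
    import yaml

    with open(out / "config.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(config, handle, sort_keys=False)
    return manifest
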