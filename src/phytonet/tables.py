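"""Readers and writers for the external table dialects the pipeline consumes.

Covered dialects: reverse-screening prediction CSVs (one file per query
ligand, SwissTargetPrediction-style headers), causal protein-interaction TSVs
(SIGNOR-style entity/effect columns), ADME property CSVs, and the pipeline's
own docking table. Header names vary across tool versions, so each reader
resolves columns through an alias table with exact-match-after-strip
semantics. Encoding is UTF-8 and the decimal separator is "." throughout.
Parsers never round or otherwise mutate numeric values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DialectError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "PCPIRecord",
    "PPIRecord",
    "PKAnnotation",
    "DockingRecord",
    "read_target_predictions",
    "write_target_predictions",
    "read_ppi_table",
    "write_ppi_table",
    "read_adme_table",
    "write_adme_table",
    "read_docking_table",
    "write_docking_table",
    "read_pcpi_table",
    "write_pcpi_table",
]


@dataclass(frozen=True)
class PCPIRecord:
    """A predicted ligand→protein interaction with its prediction probability."""

    ligand_id: str
    protein: str
    probability: float
    uniprot_id: str | None = None


@dataclass(frozen=True)
class PPIRecord:
    """A directed, signed protein→protein causal interaction."""

    source: str
    target: str
    effect: str  # "up-regulates" | "down-regulates" | "other"
    provenance: str = ""


@dataclass(frozen=True)
class PKAnnotation:
    """Pharmacokinetic attributes of one ligand (consumed, never computed)."""

    ligand_id: str
    bioavailability: float  # Abbott score in [0, 1]
    gi_absorption: str  # "high" | "low"
    logp: float  # octanol-water partition coefficient


@dataclass(frozen=True)
class DockingRecord:
    """Docking energy (kcal/mol; more negative = stronger) for one pair."""

    ligand_id: str
    protein: str
    energy: float
    probability: float


# Alias tables: first matching header (after whitespace strip) wins.
_TARGET_ALIASES = ("Common name", "Common Name", "Target", "Gene name", "gene", "protein")
_PROBABILITY_ALIASES = ("Probability*", "Probability", "probability")
_UNIPROT_ALIASES = ("Uniprot ID", "UniProt ID", "Uniprot", "uniprot_id")

_ENTITY_A_ALIASES = ("ENTITYA", "Entity A", "entity_a", "EntityA", "source")
_ENTITY_B_ALIASES = ("ENTITYB", "Entity B", "entity_b", "EntityB", "target")
_TYPE_A_ALIASES = ("TYPEA", "Type A", "type_a", "TypeA")
_TYPE_B_ALIASES = ("TYPEB", "Type B", "type_b", "TypeB")
_EFFECT_ALIASES = ("EFFECT", "Effect", "effect")
_MECHANISM_ALIASES = ("MECHANISM", "Mechanism", "mechanism", "provenance")

_MOLECULE_ALIASES = ("Molecule", "molecule", "name", "Name", "Canonical SMILES name")
_BIOAVAIL_ALIASES = ("Bioavailability Score", "bioavailability", "Bioavailability")
_GI_ALIASES = ("GI absorption", "gi_absorption", "GI Absorption")
_LOGP_ALIASES = ("Consensus Log P", "logp", "Log P", "LogP", "XLOGP3")


def _resolve(columns, aliases, what: str, required: bool = True) -> str | None:
    stripped = {str(c).strip(): c for c in columns}
    for alias in aliases:
        if alias in stripped:
            return stripped[alias]
    if required:
        raise DialectError(
            f"missing {what} column; expected one of {list(aliases)}, got {list(columns)}"
        )
    return None


def read_target_predictions(path, ligand_id: str) -> list[PCPIRecord]:
    """Read one ligand's reverse-screening predictions, dropping probability 0.

    Zero-probability rows mean "no evidence the query shares the target" and
    are counted and logged, never returned. Probabilities outside [0, 1]
    raise, naming the offending row.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    if frame.empty:
        logger.warning("prediction file %s has no data rows", path)
        return []
    target_col = _resolve(frame.columns, _TARGET_ALIASES, "target-name")
    prob_col = _resolve(frame.columns, _PROBABILITY_ALIASES, "probability")
    uniprot_col = _resolve(frame.columns, _UNIPROT_ALIASES, "uniprot", required=False)

    records: list[PCPIRecord] = []
    n_zero = 0
    for idx, row in frame.iterrows():
        prob = float(row[prob_col])
        if not 0.0 <= prob <= 1.0:
            raise InputError(f"row {idx}: probability {prob} outside [0, 1]")
        if prob == 0.0:
            n_zero += 1
            continue
        uniprot = str(row[uniprot_col]).strip() if uniprot_col else None
        records.append(
            PCPIRecord(
                ligand_id=ligand_id,
                protein=str(row[target_col]).strip().upper(),
                probability=prob,
                uniprot_id=uniprot or None,
            )
        )
    if n_zero:
        logger.info("%s: dropped %d zero-probability rows", path, n_zero)
    return records


def write_target_predictions(records: list[PCPIRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "Common name": r.protein,
                "Uniprot ID": r.uniprot_id or "",
                "Probability*": r.probability,
            }
            for r in records
        ],
        columns=["Common name", "Uniprot ID", "Probability*"],
    ).to_csv(path, index=False)


def _map_effect(raw: str) -> str:
    low = raw.strip().lower()
    if "up-regulates" in low:
        return "up-regulates"
    if "down-regulates" in low:
        return "down-regulates"
    return "other"


def read_ppi_table(path) -> list[PPIRecord]:
    """Read a causal-PPI TSV; keep only protein–protein rows.

    Effect strings containing "up-regulates"/"down-regulates" collapse onto
    those classes, everything else becomes "other". Rows where either entity
    type is not "protein" (chemicals, complexes, ...) are dropped and logged.
    """
    frame = pd.read_csv(path, sep="\t", encoding="utf-8")
    if frame.empty:
        return []
    a_col = _resolve(frame.columns, _ENTITY_A_ALIASES, "entity-A")
    b_col = _resolve(frame.columns, _ENTITY_B_ALIASES, "entity-B")
    eff_col = _resolve(frame.columns, _EFFECT_ALIASES, "effect")
    ta_col = _resolve(frame.columns, _TYPE_A_ALIASES, "type-A", required=False)
    tb_col = _resolve(frame.columns, _TYPE_B_ALIASES, "type-B", required=False)
    mech_col = _resolve(frame.columns, _MECHANISM_ALIASES, "mechanism", required=False)

    records: list[PPIRecord] = []
    n_dropped = 0
    for _, row in frame.iterrows():
        if ta_col and str(row[ta_col]).strip().lower() != "protein":
            n_dropped += 1
            continue
        if tb_col and str(row[tb_col]).strip().lower() != "protein":
            n_dropped += 1
            continue
        records.append(
            PPIRecord(
                source=str(row[a_col]).strip().upper(),
                target=str(row[b_col]).strip().upper(),
                effect=_map_effect(str(row[eff_col])),
                provenance=str(row[mech_col]).strip() if mech_col else "",
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d non protein-protein rows", path, n_dropped)
    return records


def write_ppi_table(records: list[PPIRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "ENTITYA": r.source,
                "TYPEA": "protein",
                "ENTITYB": r.target,
                "TYPEB": "protein",
                "EFFECT": r.effect,
                "MECHANISM": r.provenance,
            }
            for r in records
        ],
        columns=["ENTITYA", "TYPEA", "ENTITYB", "TYPEB", "EFFECT", "MECHANISM"],
    ).to_csv(path, sep="\t", index=False)


def read_adme_table(path, registry=None) -> list[PKAnnotation]:
    """Read an ADME CSV (bioavailability score, GI absorption, log P).

    Molecule names are resolved to ligand_ids through ``registry`` (exact
    case-insensitive name, then synonym match); unresolved names are kept
    verbatim with a warning so the caller can decide. Identical duplicate
    rows collapse to one annotation.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    if frame.empty:
        return []
    mol_col = _resolve(frame.columns, _MOLECULE_ALIASES, "molecule-name")
    bio_col = _resolve(frame.columns, _BIOAVAIL_ALIASES, "bioavailability")
    gi_col = _resolve(frame.columns, _GI_ALIASES, "GI-absorption")
    logp_col = _resolve(frame.columns, _LOGP_ALIASES, "log P")

    records: list[PKAnnotation] = []
    seen: set[PKAnnotation] = set()
    for idx, row in frame.iterrows():
        gi = str(row[gi_col]).strip().lower()
        if gi not in ("high", "low"):
            raise InputError(f"row {idx}: GI absorption {row[gi_col]!r} not in {{High, Low}}")
        name = str(row[mol_col]).strip()
        ligand_id = registry.resolve_name(name) if registry is not None else None
        if ligand_id is None:
            if registry is not None:
                logger.warning("ADME row %d: molecule %r not in registry", idx, name)
            ligand_id = name
        rec = PKAnnotation(
            ligand_id=ligand_id,
            bioavailability=float(row[bio_col]),
            gi_absorption=gi,
            logp=float(row[logp_col]),
        )
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return records


def write_adme_table(records: list[PKAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "Molecule": r.ligand_id,
                "Bioavailability Score": r.bioavailability,
                "GI absorption": r.gi_absorption.capitalize(),
                "Consensus Log P": r.logp,
            }
            for r in records
        ],
        columns=["Molecule", "Bioavailability Score", "GI absorption", "Consensus Log P"],
    ).to_csv(path, index=False)


def read_docking_table(path) -> list[DockingRecord]:
    """Read docking results: ligand_id, protein, energy (kcal/mol), probability."""
    frame = pd.read_csv(path, encoding="utf-8")
    required = {"ligand_id", "protein", "energy", "probability"}
    missing = required - set(frame.columns)
    if missing:
        raise DialectError(f"docking table missing columns: {sorted(missing)}")
    records = []
    for idx, row in frame.iterrows():
        energy = float(row["energy"])
        prob = float(row["probability"])
        if not np.isfinite(energy):
            raise InputError(f"row {idx}: non-finite docking energy")
        if not 0.0 < prob <= 1.0:
            raise InputError(f"row {idx}: probability {prob} outside (0, 1]")
        records.append(
            DockingRecord(
                ligand_id=str(row["ligand_id"]),
                protein=str(row["protein"]).strip().upper(),
                energy=energy,
                probability=prob,
            )
        )
    return records


def write_docking_table(records: list[DockingRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "protein": r.protein,
                "energy": r.energy,
                "probability": r.probability,
            }
            for r in records
        ],
        columns=["ligand_id", "protein", "energy", "probability"],
    ).to_csv(path, index=False)


def read_pcpi_table(path) -> list[PCPIRecord]:
    """Read the pipeline's own merged PCPI table."""
    frame = pd.read_csv(path, encoding="utf-8").fillna("")
    required = {"ligand_id", "protein", "probability"}
    missing = required - set(frame.columns)
    if missing:
        raise DialectError(f"PCPI table missing columns: {sorted(missing)}")
    return [
        PCPIRecord(
            ligand_id=str(row["ligand_id"]),
            protein=str(row["protein"]).strip().upper(),
            probability=float(row["probability"]),
            uniprot_id=str(row.get("uniprot_id", "")).strip() or None,
        )
        for _, row in frame.iterrows()
    ]


def write_pcpi_table(records: list[PCPIRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "protein": r.protein,
                "uniprot_id": r.uniprot_id or "",
                "probability": r.probability,
            }
            for r in records
        ],
        columns=["ligand_id", "protein", "uniprot_id", "probability"],
    ).to_csv(path, index=False)
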