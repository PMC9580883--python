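"""Ligand compilation: canonical structures, deduplication, simulated metabolism.

Medicinal-plant ingredient lists mix glycosides (cores decorated with sugar
units) and their aglycones. Because gut hydrolysis releases the aglycone, the
compiled registry keeps both: every glycoside is hydrolyzed *in silico* and
any non-sugar product becomes a first-class ligand linked to its parent.

The glycosidic-bond pattern covers O-glycosides: an exocyclic oxygen bridging
the anomeric carbon of a 5- or 6-membered saccharide ring (one ring oxygen,
ring carbons bearing at least two hydroxyl / hydroxymethyl substituents) to a
carbon outside that ring. C- and N-glycosides are deliberately left intact.
Cleavage adds one water per bond: the bridging oxygen stays on the non-sugar
side as a hydroxyl and a fresh hydroxyl caps the anomeric carbon, whose
stereocentre is unset (hydrolysis racemizes the anomeric position).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import RegistryError, StructureParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "LigandRecord",
    "HydrolysisResult",
    "LigandRegistry",
    "canonicalize_structure",
    "hydrolyze_glycosides",
    "build_registry",
    "read_ligand_table",
    "write_registry",
    "read_registry",
]


@dataclass
class LigandRecord:
    """One compiled ligand with canonical structure and provenance."""

    ligand_id: str
    name: str
    smiles: str
    ligand_class: str
    role: str
    parent_id: str | None = None
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class HydrolysisResult:
    """Products of simulated glycoside hydrolysis of one parent ligand.

    ``products`` preserves fragment multiplicity so that the heavy-atom
    balance holds: sum of product heavy atoms == parent heavy atoms +
    ``bonds_cleaved`` (one water oxygen gained per cleaved bond).
    """

    parent_id: str
    products: tuple[tuple[str, str], ...]  # (canonical SMILES, "aglycone"|"sugar")
    bonds_cleaved: int


def canonicalize_structure(smiles: str) -> str:
    """Return RDKit's canonical SMILES; identical for all encodings of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _is_saccharide_ring(mol: Chem.Mol, ring: tuple[int, ...]) -> bool:
    """5/6-ring with exactly one ring oxygen and >=2 OH/CH2OH on ring carbons."""
    if len(ring) not in (5, 6):
        return False
    atoms = [mol.GetAtomWithIdx(i) for i in ring]
    if sum(a.GetAtomicNum() == 8 for a in atoms) != 1:
        return False
    if any(a.GetAtomicNum() not in (6, 8) for a in atoms):
        return False
    ring_set = set(ring)
    n_hydroxylic = 0
    for atom in atoms:
        if atom.GetAtomicNum() != 6:
            continue
        for nb in atom.GetNeighbors():
            if nb.GetIdx() in ring_set:
                continue
            if _is_free_hydroxyl(nb):
                n_hydroxylic += 1
            elif nb.GetAtomicNum() == 6 and nb.GetDegree() == 2:
                # hydroxymethyl: exocyclic CH2 carrying a free OH
                if any(
                    nb2.GetIdx() != atom.GetIdx() and _is_free_hydroxyl(nb2)
                    for nb2 in nb.GetNeighbors()
                ):
                    n_hydroxylic += 1
    return n_hydroxylic >= 2


def _is_free_hydroxyl(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 8 and atom.GetDegree() == 1 and atom.GetTotalNumHs() >= 1


def _find_glycosidic_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(anomeric carbon idx, bridging oxygen idx) pairs, one per bridging oxygen."""
    sacc_rings = [
        set(r) for r in mol.GetRingInfo().AtomRings() if _is_saccharide_ring(mol, r)
    ]
    bonds: list[tuple[int, int]] = []
    for oxy in mol.GetAtoms():
        if oxy.GetAtomicNum() != 8 or oxy.IsInRing() or oxy.GetDegree() != 2:
            continue
        n1, n2 = oxy.GetNeighbors()
        for anomeric, other in ((n1, n2), (n2, n1)):
            if anomeric.GetAtomicNum() != 6 or other.GetAtomicNum() != 6:
                continue
            hit = False
            for ring in sacc_rings:
                if anomeric.GetIdx() in ring and other.GetIdx() not in ring:
                    # anomeric carbon sits next to the ring oxygen
                    if any(
                        nb.GetIdx() in ring and nb.GetAtomicNum() == 8
                        for nb in anomeric.GetNeighbors()
                    ):
                        hit = True
                        break
            if hit:
                bonds.append((anomeric.GetIdx(), oxy.GetIdx()))
                break  # one cleavage per bridging oxygen
    return bonds


def _cleave_all(mol: Chem.Mol, bonds: list[tuple[int, int]]) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for anomeric_idx, oxy_idx in bonds:
        rw.RemoveBond(anomeric_idx, oxy_idx)
        new_o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(anomeric_idx, new_o, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(anomeric_idx).SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _is_sugar_fragment(mol: Chem.Mol) -> bool:
    """A fragment is sugar iff it has rings and every ring is a saccharide ring."""
    rings = mol.GetRingInfo().AtomRings()
    if not rings:
        return False
    return all(_is_saccharide_ring(mol, r) for r in rings)


def hydrolyze_glycosides(
    ligand: "LigandRecord | str", exhaustive: bool = True
) -> HydrolysisResult:
    """Cleave every O-glycosidic bond, capping each side with hydroxyl.

    Accepts a :class:`LigandRecord` or a bare SMILES string. With
    ``exhaustive`` (the default) cleavage repeats until no glycosidic bond
    remains; otherwise only bonds present in the input structure are cut.
    Returns an empty product list when nothing was cleaved.
    """
    if isinstance(ligand, LigandRecord):
        parent_id, smiles = ligand.ligand_id, ligand.smiles
    else:
        parent_id, smiles = "", ligand
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}")

    bonds_cleaved = 0
    while True:
        bonds = _find_glycosidic_bonds(mol)
        if not bonds:
            break
        mol = _cleave_all(mol, bonds)
        bonds_cleaved += len(bonds)
        if not exhaustive:
            break

    if bonds_cleaved == 0:
        return HydrolysisResult(parent_id, (), 0)
    products = tuple(
        (Chem.MolToSmiles(frag), "sugar" if _is_sugar_fragment(frag) else "aglycone")
        for frag in Chem.GetMolFrags(mol, asMols=True)
    )
    return HydrolysisResult(parent_id, products, bonds_cleaved)


def _slugify(name: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "-", name.strip().lower()).strip("-")
    return slug or "ligand"


class LigandRegistry:
    """Insertion-ordered ligand collection with structure-level deduplication."""

    def __init__(self) -> None:
        self.records: dict[str, LigandRecord] = {}
        self.relations: list[tuple[str, str]] = []  # (parent_id, child_id)
        self._by_smiles: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self.records

    def get(self, ligand_id: str) -> LigandRecord:
        return self.records[ligand_id]

    def find_by_smiles(self, canonical_smiles: str) -> LigandRecord | None:
        ligand_id = self._by_smiles.get(canonical_smiles)
        return self.records[ligand_id] if ligand_id else None

    def resolve_name(self, name: str) -> str | None:
        """Case-insensitive match on primary name, then synonyms; no fuzzing."""
        wanted = name.strip().lower()
        for rec in self.records.values():
            if rec.name.strip().lower() == wanted:
                return rec.ligand_id
        for rec in self.records.values():
            if any(s.strip().lower() == wanted for s in rec.synonyms):
                return rec.ligand_id
        return None

    def _unique_id(self, name: str) -> str:
        base = _slugify(name)
        if base not in self.records:
            return base
        for i in range(2, 10_000):
            candidate = f"{base}-{i}"
            if candidate not in self.records:
                return candidate
        raise RegistryError(f"cannot allocate unique ligand_id for {name!r}")

    def add(self, record: LigandRecord) -> None:
        if record.ligand_id in self.records:
            raise RegistryError(f"duplicate ligand_id: {record.ligand_id!r}")
        self.records[record.ligand_id] = record
        self._by_smiles[record.smiles] = record.ligand_id

    def add_or_merge(
        self,
        name: str,
        smiles: str,
        ligand_class: str,
        role: str,
        parent_id: str | None = None,
    ) -> LigandRecord:
        """Register a canonical structure, merging into an existing record."""
        existing = self.find_by_smiles(smiles)
        if existing is not None:
            if name != existing.name and name not in existing.synonyms:
                existing.synonyms = existing.synonyms + (name,)
            if existing.parent_id is None and parent_id is not None:
                existing.parent_id = parent_id
            return existing
        record = LigandRecord(
            ligand_id=self._unique_id(name),
            name=name,
            smiles=smiles,
            ligand_class=ligand_class,
            role=role,
            parent_id=parent_id,
        )
        self.add(record)
        return record


def _aglycone_class(parent_class: str) -> str:
    if "glycoside" in parent_class.lower():
        return re.sub("glycoside", "aglycone", parent_class, flags=re.IGNORECASE)
    return f"{parent_class} aglycone"


def build_registry(
    raw_ligands: pd.DataFrame, exhaustive: bool = True
) -> LigandRegistry:
    """Compile a ligand table (name, smiles, class, role) into a registry.

    Structures are canonicalized, duplicates merged, and every ligand is
    hydrolyzed; each non-sugar product is registered (or merged into an
    already-listed record) with a glycoside→aglycone relation. Sugar
    fragments are never registered.
    """
    required = {"name", "smiles", "class", "role"}
    missing = required - set(raw_ligands.columns)
    if missing:
        raise RegistryError(f"ligand table missing columns: {sorted(missing)}")

    registry = LigandRegistry()
    for idx, row in raw_ligands.iterrows():
        try:
            canonical = canonicalize_structure(str(row["smiles"]))
        except StructureParseError as exc:
            raise StructureParseError(f"row {idx}: {exc}") from exc
        registry.add_or_merge(
            name=str(row["name"]),
            smiles=canonical,
            ligand_class=str(row["class"]),
            role=str(row["role"]),
        )

    for record in list(registry):
        result = hydrolyze_glycosides(record, exhaustive=exhaustive)
        if result.bonds_cleaved == 0:
            continue
        seen: set[str] = set()
        for product_smiles, kind in result.products:
            if kind == "sugar" or product_smiles in seen:
                continue
            seen.add(product_smiles)
            child = registry.add_or_merge(
                name=f"{record.name} aglycone",
                smiles=product_smiles,
                ligand_class=_aglycone_class(record.ligand_class),
                role=record.role,
                parent_id=record.ligand_id,
            )
            pair = (record.ligand_id, child.ligand_id)
            if pair not in registry.relations and child.ligand_id != record.ligand_id:
                registry.relations.append(pair)
    return registry


def read_ligand_table(path) -> pd.DataFrame:
    """Read the ligand CSV (headers: name,smiles,class,role)."""
    return pd.read_csv(path, dtype=str, encoding="utf-8")


def write_registry(registry: LigandRegistry, registry_path, relations_path) -> None:
    rows = [
        {
            "ligand_id": r.ligand_id,
            "name": r.name,
            "smiles": r.smiles,
            "class": r.ligand_class,
            "role": r.role,
            "parent_id": r.parent_id or "",
            "synonyms": ";".join(r.synonyms),
        }
        for r in registry
    ]
    pd.DataFrame(
        rows,
        columns=["ligand_id", "name", "smiles", "class", "role", "parent_id", "synonyms"],
    ).to_csv(registry_path, index=False)
    pd.DataFrame(registry.relations, columns=["parent_id", "child_id"]).to_csv(
        relations_path, index=False
    )


def read_registry(registry_path, relations_path=None) -> LigandRegistry:
    """Inverse of :func:`write_registry` (round-trips all fields)."""
    registry = LigandRegistry()
    frame = pd.read_csv(registry_path, dtype=str).fillna("")
    for _, row in frame.iterrows():
        registry.add(
            LigandRecord(
                ligand_id=row["ligand_id"],
                name=row["name"],
                smiles=row["smiles"],
                ligand_class=row["class"],
                role=row["role"],
                parent_id=row["parent_id"] or None,
                synonyms=tuple(s for s in row.get("synonyms", "").split(";") if s),
            )
        )
    if relations_path is not None:
        rel = pd.read_csv(relations_path, dtype=str)
        registry.relations = list(zip(rel["parent_id"], rel["child_id"]))
    return registry
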