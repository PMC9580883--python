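"""Dialect parsers: header aliasing, filtering rules, round-trip fidelity."""

import pandas as pd
import pytest

from phytonet.errors import DialectError, InputError
from phytonet.ligands import LigandRecord, LigandRegistry
from phytonet.tables import (
    DockingRecord,
    PCPIRecord,
    PKAnnotation,
    PPIRecord,
    read_adme_table,
    read_docking_table,
    read_ppi_table,
    read_target_predictions,
    write_adme_table,
    write_docking_table,
    write_ppi_table,
    write_target_predictions,
)


def write_csv(path, frame):
    pd.DataFrame(frame).to_csv(path, index=False)
    return path


class TestTargetPredictions:
    def test_zero_probability_rows_dropped(self, tmp_path):
        f = write_csv(
            tmp_path / "p.csv",
            {
                "Common name": ["A", "B", "C", "D", "E"],
                "Probability*": [1.0, 0.4, 0.0, 0.0, 0.2],
            },
        )
        records = read_target_predictions(f, "lig")
        assert [r.protein for r in records] == ["A", "B", "E"]
        assert all(r.ligand_id == "lig" for r in records)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("Common name,Probability*\n")
        assert read_target_predictions(f, "lig") == []

    def test_dialect_variants_parse_identically(self, tmp_path):
        a = write_csv(
            tmp_path / "a.csv", {"Common name": ["X"], "Probability*": [0.5]}
        )
        b = write_csv(tmp_path / "b.csv", {"Target": ["X"], "Probability": [0.5]})
        assert read_target_predictions(a, "l") == read_target_predictions(b, "l")

    def test_missing_probability_column_raises(self, tmp_path):
        f = write_csv(tmp_path / "bad.csv", {"Common name": ["X"], "Score": [0.5]})
        with pytest.raises(DialectError, match="Probability"):
            read_target_predictions(f, "l")

    def test_out_of_range_probability_names_row(self, tmp_path):
        f = write_csv(
            tmp_path / "bad.csv", {"Common name": ["X", "Y"], "Probability*": [0.5, 1.5]}
        )
        with pytest.raises(InputError, match="row 1"):
            read_target_predictions(f, "l")

    def test_round_trip(self, tmp_path):
        records = [PCPIRecord("l", "EGFR", 0.123456789, "P00533"), PCPIRecord("l", "MTOR", 1.0, "P42345")]
        write_target_predictions(records, tmp_path / "rt.csv")
        assert read_target_predictions(tmp_path / "rt.csv", "l") == records


class TestPPITable:
    def test_effect_phrases_collapse(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        pd.DataFrame(
            {
                "ENTITYA": ["A", "B", "C"],
                "TYPEA": ["protein"] * 3,
                "ENTITYB": ["X", "Y", "Z"],
                "TYPEB": ["protein"] * 3,
                "EFFECT": [
                    "up-regulates activity",
                    "down-regulates quantity by destabilization",
                    "binds",
                ],
            }
        ).to_csv(f, sep="\t", index=False)
        effects = [r.effect for r in read_ppi_table(f)]
        assert effects == ["up-regulates", "down-regulates", "other"]

    def test_non_protein_rows_dropped(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        pd.DataFrame(
            {
                "ENTITYA": ["caffeine", "A"],
                "TYPEA": ["chemical", "protein"],
                "ENTITYB": ["X", "Y"],
                "TYPEB": ["protein", "protein"],
                "EFFECT": ["binds", "binds"],
            }
        ).to_csv(f, sep="\t", index=False)
        records = read_ppi_table(f)
        assert [r.source for r in records] == ["A"]

    def test_empty_table(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        f.write_text("ENTITYA\tTYPEA\tENTITYB\tTYPEB\tEFFECT\n")
        assert read_ppi_table(f) == []

    def test_missing_columns_raise(self, tmp_path):
        f = tmp_path / "ppi.tsv"
        f.write_text("FOO\tBAR\n1\t2\n")
        with pytest.raises(DialectError):
            read_ppi_table(f)

    def test_round_trip(self, tmp_path):
        records = [PPIRecord("A", "B", "up-regulates", "synthetic"),
                   PPIRecord("B", "C", "other", "synthetic")]
        write_ppi_table(records, tmp_path / "rt.tsv")
        assert read_ppi_table(tmp_path / "rt.tsv") == records


class TestADMETable:
    def registry(self):
        reg = LigandRegistry()
        reg.add(LigandRecord("mol1", "Mol1", "C", "x", "phytochemical", synonyms=("first",)))
        return reg

    def test_direct_parse(self, tmp_path):
        f = write_csv(
            tmp_path / "adme.csv",
            {
                "Molecule": ["mol1"],
                "Bioavailability Score": [0.55],
                "GI absorption": ["High"],
                "Consensus Log P": [1.8],
            },
        )
        (rec,) = read_adme_table(f)
        assert rec == PKAnnotation("mol1", 0.55, "high", 1.8)

    def test_invalid_gi_value_raises(self, tmp_path):
        f = write_csv(
            tmp_path / "adme.csv",
            {
                "Molecule": ["m"],
                "Bioavailability Score": [0.5],
                "GI absorption": ["Medium"],
                "Consensus Log P": [1.0],
            },
        )
        with pytest.raises(InputError, match="Medium"):
            read_adme_table(f)

    def test_identical_duplicates_collapse(self, tmp_path):
        f = write_csv(
            tmp_path / "adme.csv",
            {
                "Molecule": ["m", "m"],
                "Bioavailability Score": [0.5, 0.5],
                "GI absorption": ["Low", "Low"],
                "Consensus Log P": [1.0, 1.0],
            },
        )
        assert len(read_adme_table(f)) == 1

    def test_name_resolution_case_insensitive(self, tmp_path):
        f = write_csv(
            tmp_path / "adme.csv",
            {
                "Molecule": ["MOL1", "FIRST", "stranger"],
                "Bioavailability Score": [0.5, 0.6, 0.7],
                "GI absorption": ["Low", "High", "Low"],
                "Consensus Log P": [1.0, 2.0, 3.0],
            },
        )
        records = read_adme_table(f, registry=self.registry())
        assert [r.ligand_id for r in records] == ["mol1", "mol1", "stranger"]

    def test_round_trip(self, tmp_path):
        records = [PKAnnotation("m", 0.55, "high", 1.8), PKAnnotation("n", 0.11, "low", -0.4)]
        write_adme_table(records, tmp_path / "rt.csv")
        assert read_adme_table(tmp_path / "rt.csv") == records


class TestDockingTable:
    def test_round_trip_and_validation(self, tmp_path):
        records = [DockingRecord("l", "EGFR", -7.85, 1.0), DockingRecord("l", "MTOR", -6.0, 0.3)]
        write_docking_table(records, tmp_path / "d.csv")
        assert read_docking_table(tmp_path / "d.csv") == records

    def test_probability_zero_rejected(self, tmp_path):
        write_csv(
            tmp_path / "d.csv",
            {"ligand_id": ["l"], "protein": ["X"], "energy": [-7.0], "probability": [0.0]},
        )
        with pytest.raises(InputError):
            read_docking_table(tmp_path / "d.csv")

    def test_missing_columns_raise(self, tmp_path):
        write_csv(tmp_path / "d.csv", {"ligand_id": ["l"], "energy": [-7.0]})
        with pytest.raises(DialectError):
            read_docking_table(tmp_path / "d.csv")
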