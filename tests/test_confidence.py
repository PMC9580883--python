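"""Docking-energy cutoffs, confidence classes, and the simplified subnetwork."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytonet import (
    ConfidenceModel,
    assemble_network,
    calibrate,
    classify_docking_confidence,
    classify_interactions,
    classify_probability_confidence,
    clean,
    compute_docking_cutoffs,
    compute_probability_regions,
    extract_high_confidence_subnetwork,
)
from phytonet.errors import CalibrationError
from phytonet.tables import DockingRecord, PCPIRecord

from conftest import toy_registry

# thresholds as printed for the worked study: soft/hard cutoffs in kcal/mol,
# probability-region bounds dimensionless
PRINTED = ConfidenceModel(
    soft_cutoff=-7.8, hard_cutoff=-6.4, prob_high_threshold=0.1263, prob_low_threshold=0.0774
)


def dock(energy, probability=1.0, ligand="l", protein="P"):
    return DockingRecord(ligand, protein, energy, probability)


class TestDockingCutoffs:
    def test_soft_is_minimum_of_probability_one_energies(self):
        soft, _ = compute_docking_cutoffs([dock(-7.8), dock(-7.4), dock(-7.0)])
        assert soft == -7.8

    def test_hard_is_mean_plus_k_sd(self):
        energies = np.array([-7.8, -7.4, -7.0])
        _, hard = compute_docking_cutoffs([dock(e) for e in energies], k_hard=3)
        assert hard == pytest.approx(energies.mean() + 3 * energies.std(ddof=0), abs=1e-12)

    def test_single_record_collapses_soft_and_hard(self):
        soft, hard = compute_docking_cutoffs([dock(-8.0)])
        assert soft == hard == -8.0

    def test_probability_below_one_ignored_for_anchoring(self):
        soft, _ = compute_docking_cutoffs([dock(-9.0, probability=0.9), dock(-7.0)])
        assert soft == -7.0

    def test_no_anchor_record_raises(self):
        with pytest.raises(CalibrationError, match="explicit"):
            compute_docking_cutoffs([dock(-9.0, probability=0.5)])

    def test_sample_sd_option(self):
        energies = np.array([-7.8, -7.4, -7.0])
        _, hard = compute_docking_cutoffs([dock(e) for e in energies], k_hard=3, ddof=1)
        assert hard == pytest.approx(energies.mean() + 3 * energies.std(ddof=1), abs=1e-12)


class TestProbabilityRegions:
    def test_degenerate_sd_zero(self):
        pairs = [("low", 0.1), ("low", 0.1), ("low", 0.1), ("medium", 0.08)]
        high, low = compute_probability_regions(pairs)
        assert high == pytest.approx(0.1)
        assert low == pytest.approx(0.08)

    def test_hand_computed_band(self):
        pairs = [("low", 0.05), ("low", 0.15), ("medium", 0.2), ("medium", 0.4)]
        high, low = compute_probability_regions(pairs, k_prob=1)
        assert high == pytest.approx(0.10 + np.std([0.05, 0.15]), abs=1e-12)
        assert low == pytest.approx(0.30 - np.std([0.2, 0.4]), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(CalibrationError, match="explicit"):
            compute_probability_regions([("low", 0.1), ("high", 0.9)])


class TestClassificationProbes:
    """Boundary behaviour around the printed thresholds."""

    EPS = 1e-9

    @pytest.mark.parametrize(
        "energy,expected",
        [
            (-8.0, "high"),
            (-7.0, "medium"),
            (-6.0, "low"),
            (-7.8 - 1e-9, "high"),
            (-7.8, "medium"),  # boundary falls to the weaker class
            (-7.8 + 1e-9, "medium"),
            (-6.4 - 1e-9, "medium"),
            (-6.4, "low"),
            (-6.4 + 1e-9, "low"),
        ],
    )
    def test_docking_classes(self, energy, expected):
        assert classify_docking_confidence(energy, PRINTED) == expected

    @pytest.mark.parametrize(
        "probability,expected",
        [
            (1.0, "high"),
            (0.10, "uncertain"),
            (0.05, "low"),
            (0.1263 + 1e-9, "high"),
            (0.1263, "uncertain"),  # boundary falls to the weaker class
            (0.1263 - 1e-9, "uncertain"),
            (0.0774 + 1e-9, "uncertain"),
            (0.0774, "low"),
            (0.0774 - 1e-9, "low"),
        ],
    )
    def test_probability_classes(self, probability, expected):
        assert classify_probability_confidence(probability, PRINTED) == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=-12, max_value=0, allow_nan=False),
        st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
    )
    def test_every_pair_gets_exactly_one_class_each(self, energy, probability):
        assert classify_docking_confidence(energy, PRINTED) in ("high", "medium", "low")
        assert classify_probability_confidence(probability, PRINTED) in (
            "high",
            "uncertain",
            "low",
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=-12, max_value=0, allow_nan=False),
        st.floats(min_value=0.01, max_value=3, allow_nan=False),
    )
    def test_monotone_in_energy(self, energy, delta):
        rank = {"high": 2, "medium": 1, "low": 0}
        stronger = classify_docking_confidence(energy - delta, PRINTED)
        weaker = classify_docking_confidence(energy, PRINTED)
        assert rank[stronger] >= rank[weaker]


class TestParameterRecovery:
    def test_cutoffs_match_closed_forms_on_synthetic_tables(self):
        rng = np.random.default_rng(42)
        anchor = rng.normal(-8.0, 0.4, size=40)
        extra = rng.normal(-6.0, 0.5, size=60)
        records = [dock(e, 1.0) for e in anchor] + [
            dock(e, p) for e, p in zip(extra, rng.uniform(0.05, 0.9, size=60))
        ]
        soft, hard = compute_docking_cutoffs(records, k_hard=3)
        assert soft == pytest.approx(anchor.min(), abs=1e-9)
        assert hard == pytest.approx(anchor.mean() + 3 * anchor.std(ddof=0), abs=1e-9)

    def test_calibrate_with_explicit_overrides(self):
        model = calibrate(
            [dock(-8.0)],
            soft_cutoff=-7.8,
            hard_cutoff=-6.4,
            prob_high_threshold=0.1263,
            prob_low_threshold=0.0774,
        )
        assert (model.soft_cutoff, model.hard_cutoff) == (-7.8, -6.4)

    def test_model_yaml_round_trip(self):
        text = PRINTED.to_yaml()
        assert ConfidenceModel.from_yaml(text) == PRINTED

    def test_inconsistent_model_rejected(self):
        with pytest.raises(CalibrationError):
            ConfidenceModel(-6.0, -7.0, 0.2, 0.1)


class TestSimplifiedSubnetwork:
    def network_and_classified(self):
        pcpis = [
            PCPIRecord("l1", "A", 1.0),  # kept: probability clause
            PCPIRecord("l2", "B", 0.3),  # kept: high docking clause
            PCPIRecord("l3", "C", 0.3),  # dropped: neither clause
        ]
        from phytonet.tables import PPIRecord

        ppis = [PPIRecord("A", "B", "up-regulates"), PPIRecord("A", "C", "down-regulates")]
        net = clean(assemble_network(pcpis, ppis, [("l1", "l2")], toy_registry(), set()))
        dockings = [
            dock(-5.0, 1.0, "l1", "A"),
            dock(-8.5, 0.3, "l2", "B"),
            dock(-7.0, 0.3, "l3", "C"),
        ]
        classified = classify_interactions(dockings, PRINTED)
        return net, classified

    def test_keep_rules(self):
        net, classified = self.network_and_classified()
        sub = extract_high_confidence_subnetwork(net, classified, PRINTED)
        pairs = {
            (u, v)
            for u, v, d in sub.graph.edges(data=True)
            if d["edge_type"] in ("PCPI", "DPI")
        }
        assert pairs == {("l1", "A"), ("l2", "B")}
        assert "l3" not in sub.graph
        assert "C" not in sub.graph

    def test_surviving_protein_and_ligand_edges_kept(self):
        net, classified = self.network_and_classified()
        sub = extract_high_confidence_subnetwork(net, classified, PRINTED)
        types = {d["edge_type"] for _, _, d in sub.graph.edges(data=True)}
        assert "PPI-up" in types  # A->B among surviving proteins
        assert "PPI-down" not in types  # C dropped
        assert "glycoside-aglycone" in types  # l1->l2 both survive

    def test_always_a_subgraph(self):
        net, classified = self.network_and_classified()
        sub = extract_high_confidence_subnetwork(net, classified, PRINTED)
        assert set(sub.graph.nodes) <= set(net.graph.nodes)
        parent_edges = {(u, v, d["edge_type"]) for u, v, d in net.graph.edges(data=True)}
        for u, v, d in sub.graph.edges(data=True):
            assert (u, v, d["edge_type"]) in parent_edges
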