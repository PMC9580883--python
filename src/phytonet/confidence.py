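"""Confidence calibration of predicted interactions against docking energies.

The idea: prediction probability 1 marks interactions already recorded in a
bioactivity database, so their docking energies anchor what a "real" binder
looks like. Two energy cutoffs follow:

* soft cutoff — the most negative docking energy among probability-1 pairs;
  anything below it binds at least as strongly as a known interaction;
* hard cutoff — the upper bound of the mean ± k·SD band (k = 3, i.e. a 99.7%
  normal band) of those energies; anything above it is weaker than nearly
  all known interactions.

Docking confidence is high below the soft cutoff, medium between the two,
low above the hard cutoff. Probability-confidence regions are then derived
from the docking classes: the high-probability threshold is the upper bound
of the mean ± k·SD band (k = 1, a 68% band) of probabilities in the *low*
docking class, and the low-probability threshold is the lower bound of the
same band in the *medium* class. Boundary values fall to the weaker class.

SD is population SD (ddof 0) by default; sample SD is available via
``ddof=1``. Both multipliers are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError
from .network import AnnotatedNetwork
from .tables import DockingRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceModel",
    "ClassifiedInteraction",
    "compute_docking_cutoffs",
    "classify_docking_confidence",
    "compute_probability_regions",
    "classify_probability_confidence",
    "classify_interactions",
    "calibrate",
    "extract_high_confidence_subnetwork",
    "write_classified_table",
]


@dataclass(frozen=True)
class ConfidenceModel:
    """Finalized cutoffs and thresholds for interaction triage."""

    soft_cutoff: float  # kcal/mol, more negative than hard
    hard_cutoff: float
    prob_high_threshold: float
    prob_low_threshold: float
    k_hard: float = 3.0
    k_prob: float = 1.0
    ddof: int = 0

    def __post_init__(self):
        if self.soft_cutoff > self.hard_cutoff:
            raise CalibrationError(
                f"soft cutoff {self.soft_cutoff} must be <= hard cutoff {self.hard_cutoff}"
            )
        if self.prob_high_threshold < self.prob_low_threshold:
            raise CalibrationError("probability thresholds out of order")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ConfidenceModel":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class ClassifiedInteraction:
    docking: DockingRecord
    docking_confidence: str  # high | medium | low
    probability_confidence: str  # high | uncertain | low


def compute_docking_cutoffs(
    dockings: list[DockingRecord], k_hard: float = 3.0, ddof: int = 0
) -> tuple[float, float]:
    """Soft/hard docking-energy cutoffs from the probability-1 records.

    soft = min energy of probability-1 records; hard = mean + k_hard·SD of
    those energies. With a single record (SD 0) the two coincide.
    """
    anchor = np.array([d.energy for d in dockings if d.probability == 1.0])
    if anchor.size == 0:
        raise CalibrationError(
            "no probability-1 docking record; supply explicit soft/hard cutoffs"
        )
    soft = float(anchor.min())
    hard = float(anchor.mean() + k_hard * anchor.std(ddof=ddof))
    return soft, hard


def classify_docking_confidence(energy: float, model: ConfidenceModel) -> str:
    """high: E < soft; medium: soft <= E < hard; low: E >= hard."""
    if energy < model.soft_cutoff:
        return "high"
    if energy < model.hard_cutoff:
        return "medium"
    return "low"


def compute_probability_regions(
    classified: "list[ClassifiedInteraction] | list[tuple[str, float]]",
    k_prob: float = 1.0,
    ddof: int = 0,
) -> tuple[float, float]:
    """Probability thresholds from the low / medium docking groups.

    high threshold = mean + k·SD of probabilities in the low docking group;
    low threshold  = mean − k·SD of probabilities in the medium group.
    Accepts classified interactions or bare (docking_confidence, probability)
    pairs.
    """
    pairs = [
        (c.docking_confidence, c.docking.probability)
        if isinstance(c, ClassifiedInteraction)
        else (c[0], c[1])
        for c in classified
    ]
    low = np.array([p for cls, p in pairs if cls == "low"])
    medium = np.array([p for cls, p in pairs if cls == "medium"])
    if low.size == 0 or medium.size == 0:
        raise CalibrationError(
            "low and medium docking groups must be non-empty; "
            "supply explicit probability thresholds"
        )
    high_thr = float(low.mean() + k_prob * low.std(ddof=ddof))
    low_thr = float(medium.mean() - k_prob * medium.std(ddof=ddof))
    return high_thr, low_thr


def classify_probability_confidence(probability: float, model: ConfidenceModel) -> str:
    """high: P > high threshold; low: P <= low threshold; uncertain between."""
    if probability > model.prob_high_threshold:
        return "high"
    if probability <= model.prob_low_threshold:
        return "low"
    return "uncertain"


def calibrate(
    dockings: list[DockingRecord],
    k_hard: float = 3.0,
    k_prob: float = 1.0,
    ddof: int = 0,
    soft_cutoff: float | None = None,
    hard_cutoff: float | None = None,
    prob_high_threshold: float | None = None,
    prob_low_threshold: float | None = None,
) -> ConfidenceModel:
    """Full calibration; any explicitly supplied value bypasses computation."""
    if soft_cutoff is None or hard_cutoff is None:
        soft, hard = compute_docking_cutoffs(dockings, k_hard=k_hard, ddof=ddof)
        soft_cutoff = soft if soft_cutoff is None else soft_cutoff
        hard_cutoff = hard if hard_cutoff is None else hard_cutoff
    if prob_high_threshold is None or prob_low_threshold is None:
        interim = ConfidenceModel(
            soft_cutoff, hard_cutoff, 1.0, 0.0, k_hard=k_hard, k_prob=k_prob, ddof=ddof
        )
        pairs = [
            (classify_docking_confidence(d.energy, interim), d.probability)
            for d in dockings
        ]
        high_thr, low_thr = compute_probability_regions(pairs, k_prob=k_prob, ddof=ddof)
        prob_high_threshold = high_thr if prob_high_threshold is None else prob_high_threshold
        prob_low_threshold = low_thr if prob_low_threshold is None else prob_low_threshold
    return ConfidenceModel(
        soft_cutoff=soft_cutoff,
        hard_cutoff=hard_cutoff,
        prob_high_threshold=prob_high_threshold,
        prob_low_threshold=prob_low_threshold,
        k_hard=k_hard,
        k_prob=k_prob,
        ddof=ddof,
    )


def classify_interactions(
    dockings: list[DockingRecord], model: ConfidenceModel
) -> list[ClassifiedInteraction]:
    return [
        ClassifiedInteraction(
            docking=d,
            docking_confidence=classify_docking_confidence(d.energy, model),
            probability_confidence=classify_probability_confidence(d.probability, model),
        )
        for d in dockings
    ]


def extract_high_confidence_subnetwork(
    network: AnnotatedNetwork,
    classified: list[ClassifiedInteraction],
    model: ConfidenceModel,
) -> AnnotatedNetwork:
    """Simplified network: high docking confidence OR probability-1 edges only.

    A ligand→protein edge survives if its docked classification is high
    docking confidence, or its prediction probability equals 1. Surviving
    endpoints are kept, causal edges among surviving proteins are kept, and
    glycoside→aglycone edges among surviving ligands are kept. Always a
    subgraph of the input.
    """
    high_pairs = {
        (c.docking.ligand_id, c.docking.protein)
        for c in classified
        if c.docking_confidence == "high"
    }
    g = network.graph
    sub = AnnotatedNetwork()
    keep_edges = []
    for u, v, k, d in g.edges(keys=True, data=True):
        if d.get("edge_type") in ("PCPI", "DPI"):
            if (u, v) in high_pairs or d.get("probability") == 1.0:
                keep_edges.append((u, v, k, d))
    keep_nodes = {u for u, _, _, _ in keep_edges} | {v for _, v, _, _ in keep_edges}
    keep_proteins = {n for n in keep_nodes if g.nodes[n].get("node_kind") == "protein"}
    keep_ligands = {n for n in keep_nodes if g.nodes[n].get("node_kind") == "ligand"}
    for u, v, k, d in g.edges(keys=True, data=True):
        et = d.get("edge_type")
        if et and et.startswith("PPI") and u in keep_proteins and v in keep_proteins:
            keep_edges.append((u, v, k, d))
        elif et == "glycoside-aglycone" and u in keep_ligands and v in keep_ligands:
            keep_edges.append((u, v, k, d))
    for n in sorted(keep_nodes):
        sub.graph.add_node(n, **g.nodes[n])
    for u, v, k, d in keep_edges:
        sub.graph.add_edge(u, v, key=k, **d)
    return sub


def write_classified_table(classified: list[ClassifiedInteraction], path) -> None:
    pd.DataFrame(
        [
            {
                "ligand_id": c.docking.ligand_id,
                "protein": c.docking.protein,
                "energy": c.docking.energy,
                "probability": c.docking.probability,
                "docking_confidence": c.docking_confidence,
                "probability_confidence": c.probability_confidence,
            }
            for c in classified
        ],
        columns=[
            "ligand_id",
            "protein",
            "energy",
            "probability",
            "docking_confidence",
            "probability_confidence",
        ],
    ).to_csv(path, index=False)
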