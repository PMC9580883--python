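"""Pathway over-representation analysis and disease-pathway filtering.

Given the set of predicted protein targets, each pathway gene set is scored
with a one-sided hypergeometric upper-tail test (probability of observing at
least the seen overlap when drawing the target list from the background
without replacement), and p-values are adjusted with Benjamini–Hochberg.
Significant pathways are candidates for the disease of interest; the chosen
pathway's overlap with the targets then restricts the interaction list to
disease-specific records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .tables import PCPIRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGeneSet",
    "EnrichmentResult",
    "read_gmt",
    "overrepresentation_test",
    "filter_to_pathway",
    "write_enrichment_results",
]


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str
    description: str
    genes: frozenset[str]  # upper-cased gene symbols


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    description: str
    overlap: frozenset[str]
    p_value: float
    adjusted_p: float


def read_gmt(path) -> list[PathwayGeneSet]:
    """Read gene sets in GMT format (id, description, tab-separated symbols)."""
    sets: list[PathwayGeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"GMT line {line_no}: need id, description, >=1 gene")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise InputError(f"GMT line {line_no}: empty gene set")
            sets.append(PathwayGeneSet(fields[0].strip(), fields[1].strip(), genes))
    return sets


def overrepresentation_test(
    targets: set[str],
    gene_sets: list[PathwayGeneSet],
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation with Benjamini–Hochberg adjustment.

    ``background`` defaults to the union of all supplied gene sets. Targets
    outside the background are dropped (logged), gene sets are intersected
    with the background before testing, and only pathways with adjusted
    p <= ``alpha`` are returned, sorted by adjusted p ascending.
    """
    if background is None:
        background = set().union(*(gs.genes for gs in gene_sets)) if gene_sets else set()
    background = {g.upper() for g in background}
    if not background:
        raise InputError("empty background gene universe")
    targets = {t.upper() for t in targets}
    outside = targets - background
    if outside:
        logger.info("dropping %d targets outside the background", len(outside))
    targets = targets & background
    if not targets:
        raise InputError("no targets inside the background universe")

    M, N = len(background), len(targets)
    raw: list[tuple[PathwayGeneSet, frozenset[str], float]] = []
    for gs in gene_sets:
        genes = gs.genes & background
        if not genes:
            continue
        overlap = frozenset(genes & targets)
        k, K = len(overlap), len(genes)
        # upper tail: P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(hypergeom.sf(k - 1, M, K, N))
        raw.append((gs, overlap, min(p, 1.0)))

    if not raw:
        return []
    _, adjusted, _, _ = multipletests([p for _, _, p in raw], method="fdr_bh")
    results = [
        EnrichmentResult(gs.pathway_id, gs.description, overlap, p, float(adj))
        for (gs, overlap, p), adj in zip(raw, adjusted)
    ]
    results = [r for r in results if r.adjusted_p <= alpha]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.pathway_id))
    return results


def filter_to_pathway(
    pcpis: list[PCPIRecord], pathway: PathwayGeneSet, overlap: set[str]
) -> list[PCPIRecord]:
    """Keep exactly the interaction records whose protein is in the overlap."""
    overlap = {g.upper() for g in overlap}
    if not overlap <= set(pathway.genes):
        raise InputError("overlap contains genes outside the pathway")
    kept = [r for r in pcpis if r.protein in overlap]
    if not kept:
        logger.warning("no interactions survive the %s filter", pathway.pathway_id)
    return kept


def write_enrichment_results(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "description": r.description,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "overlap": ";".join(sorted(r.overlap)),
            }
            for r in results
        ],
        columns=["pathway_id", "description", "p_value", "adjusted_p", "overlap"],
    ).to_csv(path, index=False)
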