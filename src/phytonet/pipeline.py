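"""End-to-end driver: compile → screen-merge → enrich → assemble → annotate
→ calibrate → export, with every intermediate written to disk.

Each stage is a pure function of the configuration and the files produced by
earlier stages, so a rerun with the same config yields byte-identical output.
A run manifest records the package version, seed, parameters and per-stage
record counts. No timestamps are written anywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_pharmacokinetics,
    annotate_protein_function,
    assign_ligand_locations,
    assign_protein_locations,
    read_function_table,
    read_location_table,
)
from .confidence import (
    calibrate,
    classify_interactions,
    extract_high_confidence_subnetwork,
    write_classified_table,
)
from .enrichment import (
    filter_to_pathway,
    overrepresentation_test,
    read_gmt,
    write_enrichment_results,
)
from .errors import ConfigError, StageError
from .ligands import build_registry, read_ligand_table, read_registry, write_registry
from .network import (
    assemble_network,
    clean,
    network_summary,
    read_network_csv,
    write_network_csv,
)
from .tables import (
    read_adme_table,
    read_docking_table,
    read_pcpi_table,
    read_target_predictions,
    write_pcpi_table,
)
from .visual import StyleMap, compute_style, layout_compartments, write_graph, write_legend

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline", "STAGES"]

_REQUIRED_INPUTS = (
    "ligands",
    "predictions_dir",
    "ppi",
    "gene_sets",
    "adme",
    "locations_primary",
    "locations_fallback",
    "functions",
    "docking",
)


def load_config(path) -> dict:
    """Read and validate the pipeline configuration file (YAML)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}
    inputs = config.get("inputs") or {}
    missing = [k for k in _REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ConfigError(f"config missing input entries: {missing}")
    base = path.parent
    resolved = {k: (base / v if not Path(v).is_absolute() else Path(v)) for k, v in inputs.items()}
    absent = [str(p) for p in resolved.values() if not p.exists()]
    if absent:
        raise ConfigError(f"input files do not exist: {absent}")
    if "pathway" not in config:
        raise ConfigError("config must name the disease pathway (key 'pathway')")
    config["inputs"] = {k: str(v) for k, v in resolved.items()}
    config.setdefault("seed", 0)
    config.setdefault("alpha", 0.05)
    config.setdefault("exhaustive_hydrolysis", True)
    config.setdefault("confidence", {})
    return config


def stage_compile(config: dict, out: Path) -> dict:
    table = read_ligand_table(config["inputs"]["ligands"])
    registry = build_registry(table, exhaustive=bool(config["exhaustive_hydrolysis"]))
    write_registry(registry, out / "registry.csv", out / "relations.csv")
    return {"ligands_in": len(table), "registry_records": len(registry),
            "glycoside_relations": len(registry.relations)}


def stage_screen_merge(config: dict, out: Path) -> dict:
    registry = read_registry(out / "registry.csv", out / "relations.csv")
    pred_dir = Path(config["inputs"]["predictions_dir"])
    records = []
    n_zero = n_missing = 0
    for rec in registry:
        f = pred_dir / f"{rec.ligand_id}.csv"
        if not f.exists():
            n_missing += 1
            logger.warning("no prediction file for %s", rec.ligand_id)
            continue
        kept = read_target_predictions(f, rec.ligand_id)
        n_raw = len(pd.read_csv(f))
        n_zero += n_raw - len(kept)
        records.extend(kept)
    write_pcpi_table(records, out / "complete_pcpis.csv")
    return {"complete_pcpis": len(records), "zero_probability_dropped": n_zero,
            "ligands_without_predictions": n_missing}


def stage_enrich(config: dict, out: Path) -> dict:
    pcpis = read_pcpi_table(out / "complete_pcpis.csv")
    gene_sets = read_gmt(config["inputs"]["gene_sets"])
    targets = {r.protein for r in pcpis}
    results = overrepresentation_test(targets, gene_sets, alpha=float(config["alpha"]))
    write_enrichment_results(results, out / "enrichment.csv")
    chosen = next((gs for gs in gene_sets if gs.pathway_id == config["pathway"]), None)
    if chosen is None:
        raise StageError(f"pathway {config['pathway']!r} not in the gene-set file")
    overlap = set(chosen.genes) & targets
    disease = filter_to_pathway(pcpis, chosen, overlap)
    write_pcpi_table(disease, out / "disease_pcpis.csv")
    return {"enriched_pathways": len(results), "overlap_proteins": len(overlap),
            "disease_pcpis": len(disease)}


def stage_assemble(config: dict, out: Path) -> dict:
    from .tables import read_ppi_table

    registry = read_registry(out / "registry.csv", out / "relations.csv")
    disease = read_pcpi_table(out / "disease_pcpis.csv")
    ppis = read_ppi_table(config["inputs"]["ppi"])
    control_ids = {
        r.ligand_id for r in registry if r.role in ("positive-control", "negative-control")
    }
    net = assemble_network(disease, ppis, registry.relations, registry, control_ids)
    net = clean(net)
    write_network_csv(net, out / "network.nodes.csv", out / "network.edges.csv")
    network_summary(net).to_csv(out / "summary.csv", index=False)
    return {"nodes": net.n_nodes, "edges": net.n_edges}


def stage_annotate(config: dict, out: Path) -> dict:
    registry = read_registry(out / "registry.csv", out / "relations.csv")
    net = read_network_csv(out / "network.nodes.csv", out / "network.edges.csv")
    primary = read_location_table(config["inputs"]["locations_primary"])
    fallback = read_location_table(config["inputs"]["locations_fallback"])
    assign_protein_locations(net, primary, fallback)
    assign_ligand_locations(net)
    pk = read_adme_table(config["inputs"]["adme"], registry=registry)
    annotate_pharmacokinetics(net, pk)
    functions = read_function_table(config["inputs"]["functions"])
    annotate_protein_function(net, functions)
    write_network_csv(net, out / "annotated.nodes.csv", out / "annotated.edges.csv")
    return {"pk_records": len(pk), "function_entries": len(functions)}


def stage_calibrate(config: dict, out: Path) -> dict:
    dockings = read_docking_table(config["inputs"]["docking"])
    conf = config.get("confidence", {})
    model = calibrate(
        dockings,
        k_hard=float(conf.get("k_hard", 3.0)),
        k_prob=float(conf.get("k_prob", 1.0)),
        ddof=int(conf.get("ddof", 0)),
        soft_cutoff=conf.get("soft_cutoff"),
        hard_cutoff=conf.get("hard_cutoff"),
        prob_high_threshold=conf.get("prob_high_threshold"),
        prob_low_threshold=conf.get("prob_low_threshold"),
    )
    (out / "confidence_model.yaml").write_text(model.to_yaml(), encoding="utf-8")
    classified = classify_interactions(dockings, model)
    write_classified_table(classified, out / "classified.csv")
    net = read_network_csv(out / "annotated.nodes.csv", out / "annotated.edges.csv")
    sub = extract_high_confidence_subnetwork(net, classified, model)
    write_network_csv(sub, out / "simplified.nodes.csv", out / "simplified.edges.csv")
    return {
        "docked": len(dockings),
        "soft_cutoff": model.soft_cutoff,
        "hard_cutoff": model.hard_cutoff,
        "prob_high_threshold": model.prob_high_threshold,
        "prob_low_threshold": model.prob_low_threshold,
        "simplified_nodes": sub.n_nodes,
        "simplified_edges": sub.n_edges,
    }


def stage_export(config: dict, out: Path) -> dict:
    net = read_network_csv(out / "annotated.nodes.csv", out / "annotated.edges.csv")
    style = StyleMap(**config.get("style", {})) if config.get("style") else StyleMap()
    compute_style(net, style)
    coords = layout_compartments(net, seed=int(config["seed"]))
    write_graph(net, coords, out / "network.graphml", fmt="graphml")
    write_graph(net, coords, out / "network.cyjs", fmt="cytoscape-json")
    write_graph(net, coords, out / "network", fmt="csv")
    write_legend(style, out / "legend.txt")
    return {"exported_nodes": net.n_nodes, "exported_edges": net.n_edges,
            "formats": ["graphml", "cytoscape-json", "csv"]}


STAGES = (
    ("compile", stage_compile),
    ("screen-merge", stage_screen_merge),
    ("enrich", stage_enrich),
    ("assemble", stage_assemble),
    ("annotate", stage_annotate),
    ("calibrate", stage_calibrate),
    ("export", stage_export),
)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run all stages in order; write a run manifest; return it.

    Stage failures propagate as :class:`StageError` after partial outputs are
    kept on disk, so a rerun can resume by inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phytonet_version": __version__,
        "seed": config.get("seed", 0),
        "parameters": {
            "pathway": config["pathway"],
            "alpha": config["alpha"],
            "exhaustive_hydrolysis": config["exhaustive_hydrolysis"],
            "confidence": config.get("confidence", {}),
        },
        "stages": {},
    }
    for name, func in STAGES:
        logger.info("stage %s", name)
        try:
            manifest["stages"][name] = func(config, out)
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            with open(out / "run_manifest.json", "w", encoding="utf-8") as handle:
                json.dump(manifest, handle, indent=1, sort_keys=True)
            raise StageError(f"stage {name} failed: {exc}") from exc
    with open(out / "run_manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
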