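# phytonet

Predict and visualize the cellular action of a medicinal plant against a
disease as an annotated phytochemical–protein interaction (PCPI) network.

Medicinal plants act through many weak, multi-target interactions rather than
a single magic bullet, which makes their mechanism hard to summarize. This
package implements a five-step network-pharmacology workflow for researchers
in natural-products and *in silico* drug discovery:

1. **Compile** a ligand list (phytochemicals plus control drugs): canonicalize
   SMILES, merge duplicate structures, and simulate gut metabolism by
   hydrolyzing every O-glycoside into its aglycone and sugar units (only
   aglycones are registered, linked to their parent glycoside).
2. **Screen** — ingest per-ligand reverse-screening prediction tables
   (SwissTargetPrediction-style CSV), keeping only predictions with
   probability *P* > 0.
3. **Build** — test predicted targets for pathway over-representation
   (hypergeometric upper tail, Benjamini–Hochberg adjusted), filter the
   interactions to a chosen disease pathway, and join them with directed,
   signed protein–protein interactions (SIGNOR-style causal TSV) using the
   disease targets as the join clause; annotate nodes with subcellular
   location, pharmacokinetics (Abbott bioavailability, GI absorption, log P)
   and protein function.
4. **Visualize** — map every annotation onto a visual channel (edge width ∝
   *P*, edge color by interaction type, node opacity ∝ log P, size by GI
   absorption, border by bioavailability, label color by function), lay nodes
   out inside a cell template by compartment, and export GraphML /
   Cytoscape JSON / CSV.
5. **Evaluate** — calibrate confidence against docking energies *E*
   (kcal/mol):

   - soft cutoff = min { *E* : *P* = 1 } — the strongest energy among
     database-known interactions;
   - hard cutoff = mean + 3·SD of those energies (the upper bound of a 99.7%
     normal band);
   - docking confidence: high (*E* < soft), medium (soft ≤ *E* < hard),
     low (*E* ≥ hard);
   - probability regions: *P*<sub>high</sub> = mean + SD of *P* in the low
     docking group, *P*<sub>low</sub> = mean − SD of *P* in the medium group;
   - a simplified high-confidence subnetwork keeps edges with high docking
     confidence or *P* = 1.

Ligands drop into the compartment of their targets by the priority rule
nucleus > mitochondrion > plasma membrane > cytoplasm (plurality fallback
otherwise). A synthetic-fixture generator emulates every input dialect with a
ground-truth manifest, so the whole pipeline runs and tests offline.

## Worked example

```sh
python examples/04_confidence_calibration.py
```

prints (abridged):

```
calibrated confidence model:
soft_cutoff: -8.4
hard_cutoff: -7.199999999999999
prob_high_threshold: 0.3819222482186906
prob_low_threshold: 0.250965270257084

classified interactions:
  sorafenib  -> EGFR   E =  -8.4 kcal/mol P = 1     docking: medium probability: high
  quercetin  -> GSK3B  E =  -7.0 kcal/mol P = 0.12  docking: low    probability: low
  saligenin  -> GSK3B  E =  -6.2 kcal/mol P = 0.45  docking: low    probability: high
```

The two probability-1 records (interactions already recorded in a bioactivity
database) anchor the cutoffs: −8.4 is their most negative energy (soft) and
−7.2 is their mean −8.1 plus three standard deviations (hard). Everything at
or above −7.2 is low docking confidence. The probability bands then come from
those groups: predictions above *P* ≈ 0.38 are high probability confidence
regardless of docking. `examples/01…05` walk through compilation, enrichment,
assembly/annotation, calibration, and the full pipeline, each printing the
numbers it computes.

There is also a thin CLI mirroring the workflow stages:

```sh
phytonet make-fixture --seed 7 --out-dir bundle/
phytonet run --config bundle/config.yaml --out-dir run/
```

`run/` then contains every intermediate (`registry.csv`, `disease_pcpis.csv`,
`network.*.csv`, `classified.csv`, `confidence_model.yaml`,
`network.graphml`, …) plus `run_manifest.json` with per-stage record counts.
Reruns are byte-identical for the same config and seed.

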