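# Methods

## Scope and model

phytonet turns heterogeneous evidence about a medicinal plant — its compiled
phytochemicals, reverse-screening target predictions, curated causal
protein–protein interactions, pathway gene sets, ADME properties and docking
energies — into one typed, directed, annotated interaction network, plus a
confidence triage of its ligand→protein edges. The pipeline assumes:

- predictions are per-ligand tables of (target, probability) with
  probability 1 reserved for interactions already recorded in the underlying
  bioactivity database;
- causal protein edges are directed and signed (up-/down-regulation, other);
- a single disease pathway (user-chosen from the gene-set file) defines the
  network's protein universe: proteins enter the network only as disease
  targets, and causal edges are kept only when **both** endpoints are disease
  targets. No intermediate proteins are pulled in.

## Simulated metabolism (glycoside hydrolysis)

Gut flora hydrolyze O-glycosides, so the compiled registry holds both each
glycoside and its aglycone. A glycosidic bond is matched structurally: an
exocyclic oxygen bridging (a) the anomeric carbon — a ring carbon adjacent to
the ring oxygen of a 5- or 6-membered ring with exactly one ring oxygen and at
least two hydroxyl/hydroxymethyl substituents on ring carbons — and (b) any
carbon outside that ring. Cleavage adds one water per bond: the bridging
oxygen stays with the non-sugar side as a hydroxyl and a fresh hydroxyl caps
the anomeric carbon, whose stereocentre is unset because hydrolysis racemizes
the anomeric position; all other stereochemistry is preserved. Cleavage
repeats to a fixed point by default (`exhaustive=True`); a single pass is
available for partial-metabolism studies. C- and N-glycosides are deliberately
not cleaved — the matcher requires the oxygen bridge.

Consequences worth knowing:

- a 1-O-acyl sugar (ester to a carboxylic acid) matches the pattern and is
  cleaved; this is chemically reasonable (esterases) but means "glycoside" is
  read broadly;
- hydrolysis products keep fragment multiplicity, so the heavy-atom balance
  Σ heavy(products) = heavy(parent) + bonds_cleaved holds exactly; duplicate
  structures merge only at registry level;
- a fragment is discarded as "sugar" iff it has at least one ring and every
  ring is a saccharide ring by the same pattern.

Canonicalization and all structure handling go through RDKit; two SMILES of
the same molecular graph always canonicalize identically, which is what
deduplication relies on.

## Over-representation test

For target set *T* drawn from background *B* (default: the union of the
supplied gene sets) and a pathway with *K* genes in *B*, the p-value is the
hypergeometric upper tail P(X ≥ |T ∩ pathway|) with X ~ Hypergeom(|B|, K,
|T|), computed by `scipy.stats.hypergeom.sf`. P-values are adjusted with
Benjamini–Hochberg (`statsmodels`); the original workflow used a web service
with its own built-in correction, which is not fully specified for
re-implementation, so BH is a documented divergence. Targets outside the
background are dropped with a log message rather than raising, since
prediction tools and gene-set files rarely share a namespace exactly.
Gene symbols are upper-cased everywhere before comparison.

## Network assembly and cleaning

The network is a `networkx.MultiDiGraph` with edge types PCPI/DPI
(ligand→protein, carrying probability; DPI when the ligand is a control
drug), PPI-up/PPI-down/PPI-other (protein→protein), and glycoside-aglycone
(ligand→ligand). Cleaning removes self-loops and collapses duplicate
(source, target, type) edges keeping the **highest probability** — the
source workflow only says duplicates are removed; keeping the strongest
evidence is this package's choice. Causal edges with effects other than
up-/down-regulation are retained as PPI-other and drawn in a neutral color.

## Annotation

Protein compartments come from a primary protein→compartment table (a spatial
proteomics map in the original study), then a fallback table (curated
annotations), then "other" with a warning; when both tables list a protein the
primary wins, and multi-compartment entries take the first listed value.
Compartment vocabulary is normalized through a synonym map (Cytosol →
cytoplasm, Cell membrane → plasma membrane, …). Ligands inherit a compartment
from their own targets: any nucleus target pins the ligand to the nucleus,
else mitochondrion, else plasma membrane, else cytoplasm; if no target is in
those four tiers the plurality compartment wins with an alphabetical
tie-break (the four-tier rule is silent on that case; the fallback makes it
total and deterministic). Pharmacokinetic attributes (Abbott bioavailability
score in [0,1], GI absorption high/low, log P = log₁₀ of the octanol/water
concentration ratio) are consumed from an ADME table, never computed.

## Confidence calibration

With docking energies *E* (kcal/mol, more negative = stronger) for a docked
subset of edges:

- soft cutoff = min{*E* : *P* = 1}; hard cutoff = mean + k·SD of those
  energies with k = 3 (a "99.7%" normal band). SD is population SD (ddof 0)
  by default because the source text equates a 68% band with one standard
  deviation; sample SD (ddof 1) and both multipliers are configurable.
- docking confidence: high iff *E* < soft; medium iff soft ≤ *E* < hard; low
  iff *E* ≥ hard. Boundary values deliberately land in the weaker class
  (conservative triage); the printed inequalities in the source are strict on
  both sides and leave boundaries undefined.
- probability regions: *P*High = mean + k·SD of probabilities in the **low**
  docking group and *P*Low = mean − k·SD in the **medium** group, k = 1.
  Classification: high iff *P* > *P*High, low iff *P* ≤ *P*Low, uncertain
  between. The model requires *P*High > *P*Low; data where the bands invert
  raise a calibration error that instructs explicit thresholds (all four
  values can be supplied in config, bypassing computation — that is also how
  the original study's printed values can be injected).
- the simplified network keeps ligand→protein edges with high docking
  confidence or *P* = 1, every incident node, causal edges among surviving
  proteins, and glycoside-aglycone edges among surviving ligands (the last is
  this package's choice; the simplified figure in the source shows parent
  structures attached by dashed lines).

A structural note: no probability-1 record can be high docking confidence,
because the soft cutoff is that group's own minimum; the strongest known
interaction sits exactly at the boundary and falls to medium.

## Visual channels and layout

Edge width is min + *P*·(max − min) over a configurable range (default 1–8);
node opacity maps log P linearly from the network's observed [min, max] onto
[0.3, 1.0] (all-equal log P maps to the top); GI absorption sets node size
(40/20); the bioavailability score is binned at 0.3 and 0.7 into red / orange
/ green borders (the source mentions high-or-medium borders qualitatively;
the bin edges are this package's defaults and configurable); ligand fill
cycles a 10-color palette over class names sorted alphabetically (the source
does not enumerate its class colors); proteins are pink squares with label
color by function. Missing pharmacokinetic values take each channel's minimum
and set a `pk_missing` marker.

The cell template is a set of named rectangles (extracellular, plasma
membrane, cytoplasm, nucleus, mitochondrion, other) in abstract canvas units,
fully configurable; nodes are placed on a per-compartment √n grid with 10%
margins and ±20% cell jitter from a seeded generator, so coordinates are
deterministic per seed, a lone node sits at its rectangle's center, and the
pairwise separation inside a compartment is at least 60% of the smaller cell
dimension. Exports: GraphML (checked by exact read-back round-trip and
structural XML inspection; formal XSD validation is not performed), a
Cytoscape-style JSON dialect, and node/edge CSVs. `None` attributes are
omitted on export. Dashes are encoded as a `line_style` attribute since not
all formats render them natively.

## Synthetic fixtures

`FixtureSpec`/`generate_fixture_bundle` emulate every input dialect for a toy
plant-vs-disease study: glycosides are built by bonding a glucosyl unit onto
real phenolic/flavonoid scaffolds (so the expected aglycone is exact by
construction, and one scaffold is also listed directly to exercise the merge
path); predictions, causal edges, ADME values, locations, functions and
docking energies are drawn from one seeded generator. Deliberate noise is
included: zero-probability prediction rows, a duplicate causal edge, a
self-loop, a chemical-entity row, and edges leaving the disease set. Docking
energies are drawn per intended confidence group; the defaults are
prob1 (−8.0, 0.3), high (−9.5, 0.2), medium (−7.9, 0.1), low (−6.0, 0.3)
kcal/mol with 8% of phytochemical predictions at probability 1 — chosen so
each intended group actually realizes its class against the cutoffs the
prob-1 group implies, and so probability-1 records remain a minority of the
medium group (see the structural note above; otherwise the probability bands
can invert, which is a property of the statistic, not a bug). The manifest's
expected counts and calibration values are computed by set arithmetic over
the constructed inputs, independently of the pipeline stages.

What the fixtures do **not** emulate: real chemistry or biology. Probabilities
are uniform, energies are Gaussian, gene assignments are random. Passing
tests demonstrate that the plumbing and the mathematics are correct, not that
predictions about any real plant or disease are.

## Problem sizes and determinism

The default fixture study is 12 phytochemicals (4 glycosides), 2 control
drugs, 15 proteins and 4 pathways — large enough that every code path
(merging, filtering, duplicate resolution, all confidence classes) is
exercised, small enough that the full pipeline runs in a few seconds. All
randomness flows through `numpy.random.default_rng(seed)`; there is no global
random state, no timestamps are written, and a rerun with the same config and
seed is byte-identical, which the tests assert file by file.

## Known limitations

- Only O-glycosidic (and 1-O-acyl) bonds are hydrolyzed; phase-I/II
  metabolism, tautomers and pKa states are out of scope.
- The over-representation background defaults to the gene-set union, which is
  smaller than a whole-genome background and makes p-values conservative
  toward pathways sharing genes with the file.
- Ligand-name matching between tables is exact (case-insensitive, synonyms
  included) with no fuzzy matching; unmatched names are logged and kept
  unresolved rather than silently joined.
- The compartment layout is a static grid, not a force-directed boundary
  layout; it optimizes nothing beyond containment and separation.
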