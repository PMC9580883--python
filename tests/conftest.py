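import pytest

from phytonet import FixtureSpec, generate_fixture_bundle, load_config, run_pipeline
from phytonet.ligands import LigandRecord, LigandRegistry
from phytonet.network import assemble_network, clean
from phytonet.tables import PCPIRecord, PPIRecord

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One synthetic input bundle shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = generate_fixture_bundle(FixtureSpec(seed=BUNDLE_SEED), out)
    return out, manifest


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline execution on the shared bundle."""
    bundle_dir, manifest = bundle
    out = tmp_path_factory.mktemp("run")
    config = load_config(bundle_dir / "config.yaml")
    run_manifest = run_pipeline(config, out)
    return out, run_manifest, manifest


def toy_registry() -> LigandRegistry:
    """Five ligands with dummy (but valid, distinct) structures."""
    registry = LigandRegistry()
    smiles = ["C", "CC", "CCC", "CCCC", "CCCCC"]
    for i, smi in enumerate(smiles, start=1):
        registry.add(
            LigandRecord(
                ligand_id=f"l{i}",
                name=f"ligand {i}",
                smiles=smi,
                ligand_class="toy",
                role="phytochemical" if i < 5 else "positive-control",
            )
        )
    return registry


def toy_network_inputs():
    """Hand-enumerated toy: 5 ligands, 4 proteins, 6 PCPIs, 3 PPIs, 1 relation.

    Expected after assembly: 9 nodes (5 ligands + proteins A-D), PPI kept
    only for A->B and C->D (A->E leaves the target set), relation (l1, l2)
    kept: 6 + 2 + 1 = 9 edges.
    """
    pcpis = [
        PCPIRecord("l1", "A", 0.5),
        PCPIRecord("l1", "B", 0.3),
        PCPIRecord("l2", "B", 1.0),
        PCPIRecord("l3", "C", 0.2),
        PCPIRecord("l4", "D", 0.9),
        PCPIRecord("l5", "A", 0.7),
    ]
    ppis = [
        PPIRecord("A", "B", "up-regulates"),
        PPIRecord("C", "D", "down-regulates"),
        PPIRecord("A", "E", "up-regulates"),  # E is not a disease target
    ]
    relations = [("l1", "l2"), ("l1", "l9")]  # second endpoint missing
    return pcpis, ppis, relations


@pytest.fixture
def toy_network():
    pcpis, ppis, relations = toy_network_inputs()
    return clean(assemble_network(pcpis, ppis, relations, toy_registry(), {"l5"}))
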