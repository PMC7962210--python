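import pytest

from numtforge.core_io import BuscoGene
from numtforge.numt import build_doubled_query
from numtforge.simulate import (
    SimulationConfig, simulate_depth, simulate_genome, simulate_hits,
    simulate_reads,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """One fully simulated dataset shared across tests (seed fixed)."""
    config = SimulationConfig(seed=1)
    assembly, mtdna, truth = simulate_genome(config)
    doubled, unit = build_doubled_query(mtdna)
    return {
        "config": config,
        "assembly": assembly,
        "mtdna": mtdna,
        "truth": truth,
        "doubled": doubled,
        "unit": unit,
        "lengths": {s.id: s.length for s in assembly},
    }


@pytest.fixture(scope="session")
def sim_depth(sim_bundle):
    return simulate_depth(sim_bundle["assembly"], sim_bundle["truth"],
                          sim_bundle["config"])


@pytest.fixture(scope="session")
def sim_hits(sim_bundle):
    return simulate_hits(sim_bundle["truth"], sim_bundle["unit"],
                         add_decoys=3, seed=1)


@pytest.fixture(scope="session")
def sim_reads(sim_bundle):
    return simulate_reads(sim_bundle["assembly"], sim_bundle["config"])


@pytest.fixture(scope="session")
def sim_busco(sim_bundle):
    return [BuscoGene(bid, "Complete", iv)
            for bid, iv in sim_bundle["truth"].busco_genes]
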