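import numpy as np
import pytest

from evescan.search import range_cull, translated_search
from evescan.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated assembly: 2 x 150 kbp contigs, 2 families x 3 copies."""
    cfg = SimulationConfig(seed=7, n_contigs=2, contig_length=150_000,
                           n_templates=2, copies_per_template=3,
                           divergence=0.02)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_sim_hits(small_sim):
    hits = translated_search(small_sim.assembly, small_sim.mcp_refs)
    return range_cull(hits)
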