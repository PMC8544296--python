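import numpy as np
import pytest

from riboshift.annotation import TranscriptIndex
from riboshift.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One small two-condition experiment shared across test modules."""
    cfg = SimConfig(n_genes=80, reads_per_library=40_000, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_txindex(small_sim):
    return TranscriptIndex(small_sim.models)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def split_libraries(sim):
    """(rpf, rna) sample->frame dicts from a SimResult."""
    rpf = {s: df for (s, lib), df in sim.alignments.items() if lib == "rpf"}
    rna = {s: df for (s, lib), df in sim.alignments.items() if lib == "rna"}
    return rpf, rna
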