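import numpy as np
import pytest

from stadia import data_io, graph as graph_mod, simulate
from stadia.model import STADIA


@pytest.fixture(scope="session")
def tiny_sim():
    """Small two-slice simulated dataset with truth, centered, plus graph."""
    ds, truth = simulate.simulate_dataset(
        seed=11, B=2, width=12, height=12, p=40, d=4, q=3, eta=1.0, potts_sweeps=30
    )
    dsc = data_io.center_genes(ds)
    g = graph_mod.assemble_adjacency(dsc)
    return dsc, truth, g


@pytest.fixture(scope="session")
def recovery_fits():
    """Default recovery scenario (two 40x40 slices, p=200, d=10, q=5,
    eta=1.5, medium batch effects), fitted for three seeds.  Shared by the
    parameter-recovery and batch-mixing acceptance checks."""
    out = []
    for seed in (1, 2, 3):
        ds, truth = simulate.simulate_dataset(seed=seed)
        dsc = data_io.center_genes(ds)
        g = graph_mod.assemble_adjacency(dsc)
        model = STADIA(dsc, n_domains=5, n_factors=10, eta=1.5, graph=g)
        res = model.fit(max_iter=30, seed=seed)
        out.append((dsc, truth, res))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
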