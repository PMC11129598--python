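import numpy as np
import pytest

import ghostintro as gi

#: Desk-scale study condition used throughout: (C1, C2, gamma) = (0.3, 0.5, 0.3).
STUDY_CELL = (0.3, 0.5, 0.3)


@pytest.fixture(scope="session")
def study_models() -> dict[str, gi.MSciModel]:
    """One model per scenario at the (0.3, 0.5, 0.3) grid cell."""
    return {
        scen: gi.from_coalescent_grid(scen, *STUDY_CELL)
        for scen in ("ghost", "inflow", "outflow")
    }


@pytest.fixture(scope="session")
def matched_models() -> dict[str, gi.MSciModel]:
    """Three scenarios matched on (gamma, C_T, C_S) = (0.3, 0.5, 1.2).

    Ghost uses a 1.2-CU ghost join, inflow C1 = 0.8 and outflow C1 = 0.3 so
    that all three share identical internal branch lengths -- the
    configuration in which topology and site-pattern summaries are provably
    identical across scenarios.
    """
    return {
        "ghost": gi.from_coalescent_grid("ghost", 0.3, 0.5, 0.3, ghost_join_cu=1.2),
        "inflow": gi.from_coalescent_grid("inflow", 0.8, 0.5, 0.3),
        "outflow": gi.from_coalescent_grid("outflow", 0.3, 0.5, 0.3),
    }


@pytest.fixture(scope="session")
def ghost_trees_small(study_models):
    """400 ghost gene trees with outgroup (shared across tests)."""
    return gi.simulate_gene_trees(study_models["ghost"], gi.SimConfig(n_loci=400, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
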