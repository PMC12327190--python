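import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from atne.evolution import ReproductionParams, TraitDistribution, TraitGrid, pair_kernel
from atne._bvn import rectangle_masses
from atne.growth import VBGMParams


@pytest.fixture
def table_params() -> VBGMParams:
    """Piscivore point growth parameters used throughout the examples."""
    return VBGMParams(l_inf=87.0, k=0.124, l0=1.7)


@pytest.fixture
def small_grid() -> TraitGrid:
    return TraitGrid((70.0, 90.0), (0.10, 0.20), 5, 5)


@pytest.fixture
def medium_params() -> ReproductionParams:
    """Medium variance levels for the piscivore with strong negative
    correlation."""
    return ReproductionParams(c_v=0.25, sigma_l_inf=3.0, sigma_k=0.030, rho=-0.7)


def naive_larvae_distribution(parents: TraitDistribution,
                              params: ReproductionParams,
                              grid: TraitGrid) -> np.ndarray:
    """Independent oracle: the literal double sum over all parent pairs, each
    component discretised through bivariate-normal rectangle masses and
    renormalised to its in-grid mass."""
    out = np.zeros(grid.shape)
    idx = np.argwhere(parents.mass > 0)
    lc, kc = grid.l_centers, grid.k_centers
    for i1, j1 in idx:
        for i2, j2 in idx:
            w = parents.mass[i1, j1] * parents.mass[i2, j2]
            mean, cov = pair_kernel((lc[i1], kc[j1]), (lc[i2], kc[j2]), params)
            sd = np.sqrt(np.diag(cov))
            r = 0.0 if sd[0] == 0 or sd[1] == 0 else cov[0, 1] / (sd[0] * sd[1])
            m = rectangle_masses(grid.l_edges, grid.k_edges, mean, sd, r)
            out += w * m / m.sum()
    return out / out.sum()
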