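import numpy as np
import pytest

from conemosaic.geometry import Parameters
from conemosaic.growth import GrowthConfig, run_growth_experiment
from conemosaic.lattice import build_columnar_packing
from conemosaic.synth import (generate_fragmented_mosaic,
                              generate_ideal_mosaic, render_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def hex_packing():
    """Small periodic hexagonal packing, isotropic, no PCP."""
    return build_columnar_packing(4, 6, Parameters(anisotropy=0.0),
                                  periodic_x=True)


@pytest.fixture()
def wall_packing():
    """Columnar packing with rigid x walls, default anisotropy."""
    return build_columnar_packing(6, 8)


def _random_pcp(packing, rng, scale=0.3):
    for e in packing.edges.values():
        for cid in e.cells:
            if cid is not None:
                e.pcp_amount[cid] = float(rng.uniform(0, scale))
    packing.invalidate()
    return packing


@pytest.fixture()
def pcp_packing(rng):
    return _random_pcp(build_columnar_packing(
        5, 6, Parameters(anisotropy=0.0), periodic_x=True), rng)


@pytest.fixture(scope="session")
def wt_experiment():
    cfg = GrowthConfig(n_columns=4, cells_per_column=12, n_established=2,
                       mode="wildtype", seed=3)
    return run_growth_experiment(cfg)


@pytest.fixture(scope="session")
def mutant_experiment():
    cfg = GrowthConfig(n_columns=4, cells_per_column=12, n_established=2,
                       mode="mutant", relaxation="fast", seed=5)
    return run_growth_experiment(cfg)


@pytest.fixture(scope="session")
def ideal_stack():
    return render_stack(generate_ideal_mosaic(10, 10), z_slices=1)


@pytest.fixture(scope="session")
def fragmented_stack():
    lattice = generate_fragmented_mosaic(n_fragments=25, mean_length=4.0,
                                         seed=3)
    return render_stack(lattice, z_slices=1), lattice
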