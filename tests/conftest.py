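import numpy as np
import pytest

from vascufab.config import (
    ChemoParams,
    ConvergenceSpec,
    FactoryParams,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Quarter-scale configuration for fast end-to-end tests.

    129 x 129 um, 750 interior cells, shortened morphogenesis and factory
    accounting; same cell geometry and kinetics as the scaled profile.
    """
    return SimulationConfig(
        domain_height=129.0,
        domain_width=129.0,
        n_circulatory=98,
        n_interior_cells=750,
        vascular_fraction=0.35,
        factory_params=FactoryParams(production_window=10.0, max_sim_time=120.0),
        convergence=ConvergenceSpec(max_steps=100),
    )


@pytest.fixture
def sparse_config(tiny_config):
    """tiny_config at ~45% area coverage, where shoving can fully resolve
    every overlap (the dense default jams like a granular packing)."""
    import dataclasses

    return dataclasses.replace(tiny_config, n_interior_cells=450)


@pytest.fixture
def quiet_chemo():
    """Chemotaxis and adhesion switched off (zero-force morphogenesis)."""
    return ChemoParams(lambda_=0.0, adhesion_strength=0.0)
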