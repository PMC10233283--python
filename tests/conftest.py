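import dataclasses

import numpy as np
import pytest

from fastmapnet import (
    Architecture,
    AreaSpec,
    ConnectivityParams,
    ExperimentConfig,
    PlasticityParams,
    build_network,
)


@pytest.fixture(scope="session")
def micro_arch() -> Architecture:
    """Three chained areas on 5x5 grids: primary -> secondary -> hub."""
    areas = (
        AreaSpec("X", "visual", "primary"),
        AreaSpec("Y", "visual", "secondary"),
        AreaSpec("Z", "visual", "hub"),
    )
    return Architecture(areas=areas, links=(("X", "Y"), ("Y", "Z")), n_side=5)


@pytest.fixture()
def micro_config() -> ExperimentConfig:
    conn = ConnectivityParams(
        within_neighborhood_radius=2,
        within_gaussian_sigma=1.5,
        within_p0=0.5,
        between_neighborhood_radius=2,
        between_gaussian_sigma=2.0,
        between_p0=0.8,
        inhib_neighborhood_radius=1,
        w_init_lo=0.0,
        w_init_hi=1.0,
        w_max=10.0,
    )
    plast = PlasticityParams(w_max=10.0)
    return dataclasses.replace(
        ExperimentConfig(), connectivity=conn, plasticity=plast
    )


@pytest.fixture()
def micro_net(micro_arch, micro_config):
    return build_network(micro_config, network_seed=7, arch=micro_arch)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
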