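import numpy as np
import pytest

from coldwater import GeneratorConfig, Reach, StreamNetwork
from coldwater.synthetic_data import (
    generate_anc_truth,
    generate_covariates,
    generate_network,
)


def make_chain(n: int, length_km: float = 1.0, incr: float = 1.0) -> StreamNetwork:
    """Linear chain reach 0 -> 1 -> ... -> n-1 (outlet), consistent areas."""
    reaches = []
    for i in range(n):
        reaches.append(
            Reach(
                reach_id=i,
                downstream_id=i + 1 if i < n - 1 else None,
                length_km=length_km,
                incremental_area_km2=incr,
                contributing_area_km2=incr * (i + 1),
                elevation_m=1000.0 - 10.0 * i,
                unit_forest="F1",
                unit_district="F1-D1",
            )
        )
    return StreamNetwork(reaches)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, n_headwaters=250, n_sites=80)


@pytest.fixture(scope="session")
def small_network(small_config):
    """499-reach seeded network with covariates and ANC truth attached."""
    net = generate_network(small_config)
    cov = generate_covariates(net, small_config)
    anc = generate_anc_truth(net, small_config)
    return net, cov, anc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
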