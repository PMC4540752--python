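import numpy as np
import pytest

from dtwalk import (
    WalkParams,
    generate_world,
    rank_held_out,
    world_to_hetnet,
)


@pytest.fixture(scope="session")
def default_world():
    """The default planted-cluster world (60x60, 4 clusters, seed 7)."""
    return generate_world()


@pytest.fixture(scope="session")
def default_net(default_world):
    """Full similarity pipeline run on the default world."""
    return world_to_hetnet(default_world)


@pytest.fixture(scope="session")
def default_params():
    return WalkParams()


@pytest.fixture(scope="session")
def held_out_records(default_world, default_net, default_params):
    """Ranks of the held-out links on the default network."""
    return rank_held_out(
        default_net, default_world.held_out_links, default_params
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
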