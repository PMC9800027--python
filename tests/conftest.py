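import numpy as np
import pytest

from rhizocloud import (
    ColorPointCloud,
    SyntheticRootParams,
    build_scaffold_geometry,
    make_phantom,
    simulate_root_cloud,
)


@pytest.fixture(scope="session")
def geometry():
    return build_scaffold_geometry()


@pytest.fixture(scope="session")
def labeled_cloud():
    """Default-condition synthetic mesocosm cloud, shared across tests."""
    return simulate_root_cloud(SyntheticRootParams(seed=1))


@pytest.fixture(scope="session")
def cylinder_phantom():
    return make_phantom("cylinder", length=50.0, radius=0.5, n_points=6000, seed=2)


@pytest.fixture(scope="session")
def y_branch_phantom():
    return make_phantom("y_branch", trunk_length=30.0, branch_length=10.0,
                        n_points=6000, seed=3)


@pytest.fixture()
def tiny_cloud():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 10, (50, 3))
    colors = rng.integers(0, 256, (50, 3))
    return ColorPointCloud(coords, colors)
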