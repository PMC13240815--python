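import numpy as np
import pytest

from treeparse3d.synthetic import PlantationSpec, generate_plantation


@pytest.fixture(scope="session")
def small_plantation():
    """2x2-tree block with labels, paired annotations and ground truth."""
    return generate_plantation(PlantationSpec(rows=2, trees_per_row=2, seed=1))


@pytest.fixture(scope="session")
def separated_pair():
    """Two widely separated trees (spacing >> crown diameter)."""
    return generate_plantation(
        PlantationSpec(rows=1, trees_per_row=2, tree_spacing=8.0,
                       growth_stage_mix=(0.0, 1.0), seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
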