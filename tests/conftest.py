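import numpy as np
import pytest

from histoquant.atlas import AtlasVolume, build_ontology


@pytest.fixture
def tiny_volume():
    """4×4×4 volume with IDs {0, 1, 2}: 1 fills x<2, 2 fills x>=2, shell of 0."""
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[0:2, 1:3, 1:3] = 1
    labels[2:4, 1:3, 1:3] = 2
    return AtlasVolume(labels=labels, voxel_size_um=25.0)


@pytest.fixture
def ten_node_ontology():
    """Depth-4 tree: 1 → {2, 3}; 2 → {4, 5}; 4 → {6, 7}; 3 → {8, 9}; 8 → {10}."""
    return build_ontology(
        [
            (1, "root", None),
            (2, "a", 1),
            (3, "b", 1),
            (4, "aa", 2),
            (5, "ab", 2),
            (6, "aaa", 4),
            (7, "aab", 4),
            (8, "ba", 3),
            (9, "bb", 3),
            (10, "baa", 8),
        ]
    )


@pytest.fixture
def two_region_ontology():
    return build_ontology([(3, "root", None), (1, "left", 3), (2, "right", 3)])
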