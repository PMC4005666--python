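import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kjunction.fixtures import HelixSpec, build_ideal_duplex, build_two_helix_scene
from kjunction.pairing import RelativeTransform, detect_base_pairs, enumerate_helix_segments
from kjunction.search import default_pattern

DUPLEX_SEQ = "GGCAUCGAUGCU"


@pytest.fixture(scope="session")
def duplex():
    """12-bp ideal A-form duplex along +z."""
    return build_ideal_duplex(HelixSpec(DUPLEX_SEQ))


@pytest.fixture(scope="session")
def duplex_pairs(duplex):
    return detect_base_pairs(duplex)


@pytest.fixture(scope="session")
def duplex_segments(duplex, duplex_pairs):
    return enumerate_helix_segments(duplex_pairs, duplex)


@pytest.fixture(scope="session")
def pattern():
    return default_pattern()


@pytest.fixture(scope="session")
def planted_scene(pattern):
    """Two-helix scene planted exactly at the shipped pattern entry."""
    scene, _ = build_two_helix_scene(
        HelixSpec(DUPLEX_SEQ), HelixSpec("GCGAUCGAUCGC"),
        pattern.entries[0], anchor_a=5, anchor_b=5)
    return scene


def random_rigid(rng) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation and a translation within +-50 A."""
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-50, 50, 3)


def random_transform(rng) -> RelativeTransform:
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return RelativeTransform(rng.uniform(-15, 15, 3), rot)
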