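import numpy as np
import pytest

from autotax.fixtures import LineageSpec, make_synthetic_world
from autotax.pipeline import build_database


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: 2 phyla x 2 genera x 2 species, with planted
    error variant, singleton, chimera, junk read and mixed strands."""
    return make_synthetic_world(LineageSpec(), seed=0)


@pytest.fixture(scope="session")
def pipeline_result(world):
    """A full create run (including the experimental FL-OTU branch)."""
    return build_database(
        world.pool, world.backbone, world.typestrains, include_otus=True
    )


@pytest.fixture(scope="session")
def flasv_db(world):
    """The designed FL-ASVs with their expected complete taxonomies."""
    return [
        (rec, world.expected_profiles[rec.id]) for rec in world.expected_flasvs
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def substituted(seq, positions, rng):
    chars = list(seq)
    for p in positions:
        chars[p] = [b for b in "ACGT" if b != chars[p]][rng.integers(0, 3)]
    return "".join(chars)
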