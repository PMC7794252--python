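import numpy as np
import pytest

from tnscreen import Feature, FeatureCatalog, GenomeModel, ScreenConfig


@pytest.fixture
def small_genome():
    # GATTACA has a single TA at position 3
    return GenomeModel("mini", "GATTACA")


@pytest.fixture
def tag_genome():
    # worked example genome for the tag conventions: TA at position 4
    return GenomeModel("tagdemo", "AACGTAGGCTACGT")


@pytest.fixture
def tiled_catalog():
    feats = [
        Feature("geneA", "gene", 10, 30, "+"),
        Feature("geneB", "gene", 50, 80, "-"),
    ]
    from tnscreen import build_intergenic_regions

    inter = build_intergenic_regions(feats, 100)
    return FeatureCatalog(feats + inter, "mini", 100)


@pytest.fixture
def desk_config():
    return ScreenConfig(rng_seed=7)


def random_genome(rng: np.random.Generator, length: int, gid: str = "rand"):
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeModel(gid, lut[rng.integers(0, 4, length)].tobytes().decode())
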