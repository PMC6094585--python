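import numpy as np
import pytest

from ontoalign import FixtureConfig, generate_fixture
from ontoalign.embeddings import WordVectorTable


@pytest.fixture(scope="session")
def small_fixture():
    """A 12-concept fixture with no planted difficulty; fast and exact."""
    cfg = FixtureConfig(
        n_concepts=12,
        confounder_fraction=0.0,
        oov_fraction=0.0,
        unmatched_fraction=0.0,
        similarity_noise=0.02,
        lexicon_coverage=1.0,
        lexicon_coverage_hard=1.0,
        seed=11,
    )
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def default_fixture():
    """A fixture at the generator's default study conditions."""
    return generate_fixture(FixtureConfig(n_concepts=40, confounder_fraction=0.4, seed=3))


@pytest.fixture()
def tiny_table():
    rng = np.random.default_rng(0)
    words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    return WordVectorTable({w: i for i, w in enumerate(words)}, rng.normal(size=(6, 4)))
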