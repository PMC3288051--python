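import numpy as np
import pytest

from regionpls import BlockSpec, PathModel, build_haplotype_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def two_block_model():
    """Two 3-manifest reflective blocks with one inner path."""
    return PathModel(
        blocks=(BlockSpec("L1", ("a", "b", "c")),
                BlockSpec("L2", ("d", "e", "f"))),
        inner_paths=(("L1", "L2"),),
    )


@pytest.fixture
def mvn_fixture(rng):
    """Seeded 200 x 6 correlated-normal matrix for two 3-manifest blocks."""
    A = rng.standard_normal((6, 6))
    cov = A @ A.T + 6 * np.eye(6)
    return rng.multivariate_normal(np.zeros(6), cov, size=200)


@pytest.fixture(scope="session")
def pool():
    """The default 24-SNP LD-structured region shared by simulation tests."""
    return build_haplotype_pool(seed=1)


def single_indicator_model():
    return PathModel(
        blocks=(BlockSpec("L1", ("x",)), BlockSpec("L2", ("y",))),
        inner_paths=(("L1", "L2"),),
    )
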