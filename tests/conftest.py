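import numpy as np
import pytest

from lnside import DatasetBundle, GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_bundle() -> DatasetBundle:
    """The generator's default study conditions (200 drugs, 2 views, seed 7)."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle() -> DatasetBundle:
    """A fast 40-drug bundle for CV and integration tests."""
    return generate(
        GeneratorConfig(
            n_drugs=40,
            n_side_effects=20,
            n_clusters=4,
            descriptors_per_view=(30, 30),
            view_informativeness=(0.9, 0.0),
            seed=13,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_binary_feature(rng, n, p, view_name="v"):
    from lnside import FeatureMatrix

    values = rng.integers(0, 2, size=(n, p))
    values[:, 0] = 1  # avoid all-zero rows and their warning
    return FeatureMatrix(
        [f"d{i}" for i in range(n)], [f"f{j}" for j in range(p)], values, view_name
    )
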