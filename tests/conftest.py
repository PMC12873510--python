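import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orthocompare.synthetic_data import SpeciesConfig, SyntheticConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """A fast, scaled-down version of the default study conditions."""
    base = dict(
        species_a=SpeciesConfig("cephalotus_like", SyntheticConfig().species_a.tissues, n_genes=400),
        species_b=SpeciesConfig("nepenthes_like", SyntheticConfig().species_b.tissues, n_genes=400),
        n_orthogroups=220,
        n_shared_up=20,
        n_shared_down=8,
        n_conflict=5,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_counts():
    """8 genes x 3 samples with uneven composition."""
    rng = np.random.default_rng(5)
    mat = rng.integers(1, 400, size=(8, 3))
    mat[0, 0] = 2000  # composition outlier
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(8)], columns=["s1", "s2", "s3"])
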