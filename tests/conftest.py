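import numpy as np
import pandas as pd
import pytest

from coexcross.synthetic import SimulationConfig, simulate


def single_tissue_config(**overrides) -> SimulationConfig:
    """A one-tissue-focused config: every module active in tissue A."""
    n_mod = len(overrides.get("module_sizes", (60,) * 5))
    defaults = dict(
        n_genes=300,
        module_sizes=(60,) * 5,
        sfari_modules=(1,),
        dvmt_modules=(2,),
        tissue_a_modules=tuple(range(1, n_mod + 1)),
        tissue_b_modules=tuple(range(1, n_mod + 1)),
        crosstalk_pairs=(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def null_config(**overrides) -> SimulationConfig:
    """Large unstructured gene set: no co-expression, configurable DE."""
    defaults = dict(
        n_genes=2000,
        module_sizes=(10,),
        module_loading=0.0,
        nb_dispersion=0.2,
        sfari_modules=(1,),
        dvmt_modules=(1,),
        tissue_a_modules=(1,),
        tissue_b_modules=(1,),
        crosstalk_pairs=(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_study():
    """The standing two-tissue synthetic study used across integration tests."""
    return simulate(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_counts():
    """4 genes x 4 samples with hand-checkable structure."""
    return pd.DataFrame(
        {
            "s1": [10, 20, 5, 0],
            "s2": [12, 18, 6, 0],
            "s3": [11, 22, 4, 0],
            "s4": [9, 21, 5, 0],
        },
        index=pd.Index(["gA", "gB", "gC", "gZero"], name="gene_id"),
    )
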