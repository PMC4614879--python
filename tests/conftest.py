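import numpy as np
import pytest

from codmix import synthdata
from codmix.genio import GenotypeTable, LifeTable


@pytest.fixture(scope="session")
def baseline_pair():
    """Well-separated 4-population baseline with its true frequencies."""
    return synthdata.gen_baselines(
        n_pops=4, n_loci=40, fct=0.15, n_per_pop=30, seed=11
    )


@pytest.fixture(scope="session")
def default_life_table() -> LifeTable:
    return synthdata.gen_life_table()


@pytest.fixture()
def tiny_table() -> GenotypeTable:
    calls = np.array(
        [
            [2, 1, 0],
            [2, 2, np.nan],
            [0, 0, 2],
            [0, 1, 2],
        ],
        dtype=float,
    )
    return GenotypeTable(
        individual_ids=["a1", "a2", "b1", "b2"],
        locus_ids=["L1", "L2", "L3"],
        calls=calls,
        group_labels=["P1", "P1", "P2", "P2"],
    )


@pytest.fixture(scope="session")
def environment():
    return synthdata.gen_environment(shape=(10, 6), seed=21)


def random_life_table(rng: np.random.Generator) -> LifeTable:
    """Independent random life table used by several oracle tests."""
    n = int(rng.integers(4, 11))
    ages = np.arange(3, 3 + n)
    return LifeTable(
        ages=ages,
        M=rng.uniform(0.05, 0.5, n),
        s=rng.uniform(0.1, 2.0, n),
        w=rng.uniform(0.2, 10.0, n),
        m=np.sort(rng.uniform(0.0, 1.0, n)),
    )
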