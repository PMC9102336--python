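import numpy as np
import pytest

from funcblup import Pedigree, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def trio_pedigree():
    """Sire, dam, one offspring."""
    return Pedigree([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture
def fullsib_mating_pedigree():
    """Unrelated parents, two full sibs, and an offspring of the sib mating."""
    return Pedigree(
        [
            ("p1", "0", "0"),
            ("p2", "0", "0"),
            ("c1", "p1", "p2"),
            ("c2", "p1", "p2"),
            ("x", "c1", "c2"),
        ]
    )


@pytest.fixture
def small_cfg():
    return SimulationConfig(
        n_founders=12,
        n_generations=2,
        n_snp=60,
        n_chromosomes=3,
        n_genes=24,
        n_terms=6,
        missing_rate=0.0,
        seed=77,
    )
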