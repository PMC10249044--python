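import numpy as np
import pandas as pd
import pytest

from cavityepp.genotypes import GenotypeMatrix
from cavityepp.synthetic_data import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A small error-free simulated population shared across tests."""
    cfg = SimulationConfig(
        n_pairs_per_plot=10,
        n_autosomal_loci=1200,
        n_sexlinked_loci=15,
        epp_rate=0.10,
        parasitism_rate=0.0,
        unsampled_father_rate=0.0,
        missing_rate=0.0,
        error_rate=0.0,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture()
def tiny_matrix():
    """Deterministic 6x8 dosage matrix with some missingness."""
    rng = np.random.default_rng(11)
    dos = rng.integers(0, 3, size=(6, 8)).astype(float)
    dos[0, 1] = np.nan
    dos[3, 5] = np.nan
    ids = [f"ind{i}" for i in range(6)]
    loci = [f"L{j}" for j in range(8)]
    return GenotypeMatrix(ids=ids, loci=loci, dosages=dos)


@pytest.fixture()
def nuclear_family_records():
    """One nest: two parents and five nestlings."""
    return pd.DataFrame(
        [
            {
                "nest_id": "N1",
                "year": 2018,
                "mother_id": "mom",
                "father_id": "dad",
                "offspring_ids": ";".join(f"chick{i}" for i in range(1, 6)),
            }
        ]
    )
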