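import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from ibrscape.genotypes import GenotypeTable  # noqa: E402
from ibrscape.synthgen import (make_landscape, sample_locations,  # noqa: E402
                               simulate_genotypes)

MINE_SCHEDULE = {1979: 0, 2011: 80, 2014: 130, 2016: 180}


def genotable(dosages, qual=90.0, depth=100.0):
    """Tiny GenotypeTable from a nested dosage list."""
    d = np.asarray(dosages, dtype=np.int8)
    loci = pd.DataFrame({
        "id": [f"l{i}" for i in range(d.shape[1])],
        "pos": np.arange(1, d.shape[1] + 1),
        "qual": qual, "mean_depth": depth,
    })
    return GenotypeTable(d, loci)


@pytest.fixture(scope="session")
def landscape():
    """40x40 crescent landscape with the standard mine growth schedule."""
    return make_landscape(grid_size=40, mine_growth_schedule=MINE_SCHEDULE,
                          seed=5)


@pytest.fixture(scope="session")
def samples(landscape):
    return sample_locations(landscape, n=30, min_dist=2.0, seed=2)


@pytest.fixture(scope="session")
def unstructured_geno(landscape, samples):
    """Panmictic genotypes: K=1, no spatial signal."""
    landscape_flat = make_landscape(grid_size=40,
                                    mine_growth_schedule=MINE_SCHEDULE,
                                    seed=5, cluster_params={"K": 1},
                                    gp_params={"sigma2": 0.0})
    geno, record = simulate_genotypes(landscape_flat, samples, n_loci=400,
                                      seed=7)
    return geno, record


@pytest.fixture(scope="session")
def two_cluster_geno(samples):
    """Two clusters at strong differentiation for structure tests."""
    truth = make_landscape(grid_size=40, mine_growth_schedule=MINE_SCHEDULE,
                           seed=5, cluster_params={"K": 2, "fst": 0.3},
                           gp_params={"sigma2": 0.0})
    geno, record = simulate_genotypes(truth, samples, n_loci=1000, seed=11)
    return geno, record
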