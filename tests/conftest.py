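import random

import numpy as np
import pytest

from masterblaster import (
    CascadeConfig,
    SimSpec,
    load_substitution_matrix,
    make_chain_fixture,
    run_master_blaster,
    simulate_database,
)
from masterblaster.alphabet import AMINO_ACIDS
from masterblaster.synthetic import label_map_of


@pytest.fixture(scope="session")
def matrix():
    return load_substitution_matrix("BLOSUM62")


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


@pytest.fixture(scope="session")
def chain_fixture():
    return make_chain_fixture(seed=1)


@pytest.fixture(scope="session")
def sim_db():
    return simulate_database(SimSpec(seed=1))


@pytest.fixture(scope="session")
def sim_labels(sim_db):
    return label_map_of(sim_db)


@pytest.fixture(scope="session")
def sim_hit_tables(sim_db, matrix):
    """Baseline and cascade hit tables for every query of the simulated db."""
    baseline_cfg = CascadeConfig(max_generations=1, max_profiles_per_generation=0)
    cascade_cfg = CascadeConfig()
    baseline, cascade = {}, {}
    for query in sim_db:
        baseline[query.id] = run_master_blaster(
            query, sim_db, matrix, baseline_cfg
        ).final_table
        cascade[query.id] = run_master_blaster(
            query, sim_db, matrix, cascade_cfg
        ).final_table
    return baseline, cascade


@pytest.fixture()
def rng():
    return random.Random(20240917)


@pytest.fixture()
def nprng():
    return np.random.default_rng(20240917)
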