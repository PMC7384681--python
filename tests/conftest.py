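import numpy as np
import pytest

import perturbnet as pn
from perturbnet import synthetic as syn


@pytest.fixture(scope="session")
def small_truth():
    """10 molecular + 2 phenotypic nodes, 4 drugs: the desk-scale study."""
    spec = pn.GroundTruthSpec(
        n_molec=10, n_phen=2, n_drug=4, edge_density=0.10,
        drug_target_count=3, seed=3,
    )
    return pn.generate_ground_truth(spec)


@pytest.fixture(scope="session")
def small_design():
    """4-drug single+pairwise design without control: 14 conditions."""
    return syn.demo_design(4, include_control=False)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_design):
    """Noisy simulated dataset on the study time grids (noise sd 0.05)."""
    return pn.simulate_dataset(small_truth, small_design, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def tiny_truth():
    """4 molecular + 1 phenotype, 2 drugs: cheap enough for brute force."""
    spec = pn.GroundTruthSpec(
        n_molec=4, n_phen=1, n_drug=2, edge_density=0.5,
        drug_target_count=2, seed=11,
    )
    return pn.generate_ground_truth(spec)


@pytest.fixture(scope="session")
def tiny_design():
    return syn.demo_design(2, include_control=False)
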