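import numpy as np
import pytest

from pgifam import sim
from pgifam.data import SNPPanel, WeightSet


@pytest.fixture(scope="session")
def small_panel() -> SNPPanel:
    return sim.random_panel(100, seed=11, theta_mode="zero")


@pytest.fixture(scope="session")
def confounded_panel() -> SNPPanel:
    """Panel with parental effects not proportional to the direct effects."""
    return sim.random_panel(100, seed=12, theta_mode="mixed", theta_scale=0.3)


@pytest.fixture(scope="session")
def trio_data(confounded_panel):
    """Trio families (one child each) with a confounded phenotype."""
    return sim.make_trio_cohort(confounded_panel, 1500, 0.4, seed=21)


@pytest.fixture(scope="session")
def sib_data(confounded_panel):
    """Two-sibling families with IBD bookkeeping."""
    return sim.make_trio_cohort(confounded_panel, 800, 0.4, seed=22, n_children=2)


@pytest.fixture(scope="session")
def true_mu_weights(confounded_panel) -> WeightSet:
    return WeightSet.from_panel(confounded_panel, "mu")


@pytest.fixture(scope="session")
def true_gamma_weights(confounded_panel) -> WeightSet:
    return WeightSet.from_panel(confounded_panel, "gamma")


def uniform_dosage_cohort(dosages, snp_ids=None):
    """Tiny hand-built unrelated cohort from an explicit dosage matrix."""
    from pgifam.data import FamilyCohort

    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snp_ids = snp_ids or [f"rs{j + 1}" for j in range(m)]
    return FamilyCohort(
        individual_id=np.array([f"i{k}" for k in range(n)], dtype=object),
        family_id=np.array([f"f{k}" for k in range(n)], dtype=object),
        role=np.full(n, "unrelated", dtype=object),
        dosage=dosages,
        snp_id=np.asarray(snp_ids, dtype=object),
    )
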