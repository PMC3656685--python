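import pytest

from dupred.synthetic import (
    SPECIES_TREE_NEWICK,
    CohortConfig,
    simulate_cohort,
)
from dupred.trees import parse_newick


@pytest.fixture(scope="session")
def species_tree():
    return parse_newick(SPECIES_TREE_NEWICK)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with the default effect sizes, shared across tests."""
    return simulate_cohort(CohortConfig(n_families=40, n_singletons=20, seed=7))


def null_config(**overrides) -> CohortConfig:
    """Cohort config with every MD/ND effect knob equalized (no effect)."""
    base = dict(
        rho_md=0.2,
        rho_nd=0.2,
        go_overlap_md=0.3,
        go_overlap_nd=0.3,
        ppi_overlap_md=0.2,
        ppi_overlap_nd=0.2,
        dnds_md=0.3,
        dnds_nd=0.3,
        complex_comember_md=0.18,
        complex_comember_nd=0.18,
        ortholog_dn_mean_md=0.07,
        ortholog_dn_mean_nd=0.07,
        p_disease_singleton=0.2,
        p_disease=0.2,
    )
    base.update(overrides)
    return CohortConfig(**base)
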