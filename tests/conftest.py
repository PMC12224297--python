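import pytest

from bgcbeacon.synthetic_data import SimConfig, generate_genomes


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-family synthetic cohort shared across read-only tests."""
    cfg = SimConfig(
        n_genomes=3,
        genes_per_genome=60,
        family_counts={"smallSARP": 25, "mediumSARP": 15, "TetR_C_33": 12, "XRE": 12},
        family_p_in={"smallSARP": 0.82, "mediumSARP": 0.5, "TetR_C_33": 0.2, "XRE": 0.3},
        n_hidden_per_genome=1,
        seed=11,
    )
    return generate_genomes(cfg)
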