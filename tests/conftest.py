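import numpy as np
import pytest

from lncdbs.cohort import CohortConfig, generate_cohort


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small cohort shared by read-only tests (oracle-friendly sizes)."""
    cfg = CohortConfig(seed=42, n_species=3, n_genes=4, n_lncrnas=3,
                       targets_per_lncrna=2, promoter_len=1500,
                       planted_site_len=60, lncrna_len=300, flank=6000,
                       n_ancient=1, planted_identity=1.0, ablation_rate=0.5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
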