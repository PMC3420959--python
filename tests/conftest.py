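import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from talenkit.fixtures import (
    make_deletion_allele,
    make_design_gene,
    make_target_region,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design_fixture():
    """A synthetic gene guaranteed to contain exactly one TALEN site."""
    return make_design_gene(1, n_sites=1)


@pytest.fixture(scope="session")
def target_setup():
    """(region, site, amplicon) for a realistic, amplicon-feasible target."""
    return make_target_region(11)


@pytest.fixture(scope="session")
def het_pool_setup(target_setup):
    """WT amplicon plus an 18 bp-deletion allele, site in amplicon coords."""
    region, site, amp = target_setup
    site_in_amp = site.shifted(-amp.start)
    allele = make_deletion_allele(site_in_amp, del_len=18)
    return amp.seq, site_in_amp, allele


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
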