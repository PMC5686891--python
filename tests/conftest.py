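import numpy as np
import pytest

from transbalance.models import (
    BalancedLocus,
    DemographicModel,
    EpochSchedule,
    MutationModel,
    model_m1,
)


@pytest.fixture(scope="session")
def m1():
    return model_m1()


@pytest.fixture(scope="session")
def mut():
    return MutationModel()


@pytest.fixture(scope="session")
def mut_flat():
    """No CpG heterogeneity: clean closed-form expectations."""
    return MutationModel(mu_base=7e-9, cpg_multiplier=1.0)


@pytest.fixture(scope="session")
def panmictic_small():
    """Single constant-size population of 100,000 haploid lineages."""
    sched = EpochSchedule(((0.0, 100_000.0),))
    return DemographicModel(sched, sched, split_time=0.0, ancestral_size=100_000.0)


@pytest.fixture(scope="session")
def balanced_locus(m1):
    return BalancedLocus(
        position=50, class_frequency=0.5, origin_time=10 * m1.split_time,
        exchange_rate=0.0,
    )
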