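import dataclasses

import pytest

from betameth import SimConfig, build_covariates, simulate_cohort

# one small cohort shared by the integration-flavoured tests
SMALL = SimConfig(
    n_cpgs=300,
    n_genes=300,
    n_expr_samples=120,
    n_snps=60,
    module_sizes=(60, 40, 30, 25, 20),
    signature_size=80,
    signature_module_overlap=25,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_covars(small_bundle):
    return build_covariates(small_bundle)


def small_config(**overrides) -> SimConfig:
    return dataclasses.replace(SMALL, **overrides)
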