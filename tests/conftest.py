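"""Shared fixtures: small simulated datasets and one contaminated fixture.

Everything is generated at test time with fixed seeds; the heavier
contaminated three-population fixture is session-scoped because the
projection-pursuit fit on a 1000 x 2000 genotype matrix is the most
expensive single step in the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import robustps as rps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def s2_small():
    """A clean S2 dataset at reduced SNP counts for quick pipeline tests."""
    gen = np.random.default_rng(777)
    scen = rps.scenario("S2", n_inference_snps=600, n_testing_snps=60)
    return rps.simulate_discrete(scen, gen)


@pytest.fixture(scope="session")
def s4_contaminated():
    """S4 with 5% injected subject outliers at the standard study scale."""
    gen = np.random.default_rng(2024)
    scen = rps.scenario("S4", n_testing_snps=100)
    ds = rps.simulate_discrete(scen, gen)
    return rps.inject_dataset_outliers(ds, rps.OutlierInjectionConfig(), gen)


@pytest.fixture(scope="session")
def s4_grid_fit(s4_contaminated):
    """GRID robust PCA fitted on the contaminated S4 inference block."""
    est = rps.PPRobustPCA(n_components=5, algorithm="grid")
    est.fit(s4_contaminated.inference)
    return est
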