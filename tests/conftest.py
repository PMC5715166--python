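import numpy as np
import pytest

from burstlangevin import GeneParams, RegulatedNetworkParams


@pytest.fixture(scope="session")
def fig1_params() -> GeneParams:
    """Reference single gene: p_bar=100, b_m=2, b_p=10."""
    return GeneParams(k_g=5, gamma_g=95, k_m=200, gamma_m=10, k_p=100, gamma_p=1)


@pytest.fixture(scope="session")
def scan_params() -> GeneParams:
    """Scan-grid base gene (gamma_g=100): b_m=2, b_p=10, p_bar=100."""
    return GeneParams.from_burst_sizes(
        k_g=5, gamma_g=100, gamma_m=10, gamma_p=1, b_m=2, b_p=10
    )


@pytest.fixture(scope="session")
def cheap_params() -> GeneParams:
    """Small-rate gene whose SSA is extremely fast (for oracle comparisons)."""
    return GeneParams(k_g=2, gamma_g=4, k_m=10, gamma_m=2, k_p=4, gamma_p=1)


@pytest.fixture(scope="session")
def bimodal_params() -> GeneParams:
    """Slow promoter switching: k_g = gamma_g = 0.1 gamma_p, gamma_m = 10 gamma_p."""
    return GeneParams(k_g=0.1, gamma_g=0.1, k_m=20, gamma_m=10, k_p=100, gamma_p=1)


@pytest.fixture(scope="session")
def repression_net() -> RegulatedNetworkParams:
    """Two-gene repression network at the scan corner b_m1=1, b_p1=1."""
    up = GeneParams.from_burst_sizes(
        k_g=5, gamma_g=100, gamma_m=10, gamma_p=1, b_m=1, b_p=1
    )
    dn = GeneParams(k_g=5, gamma_g=100, k_m=200, gamma_m=10, k_p=100, gamma_p=1)
    return RegulatedNetworkParams(upstream=up, downstream=dn, K=200, n_H=3, k_l=60)
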