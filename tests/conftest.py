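import numpy as np
import pytest

from msfinemap import MultiStudyLocus, NcpModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ncp():
    return NcpModel(ncp_scale=5.2, tau_sq=0.52)


@pytest.fixture
def tiny_locus():
    """Three independent SNPs in two studies, one clear signal."""
    snp_ids = ["rs1", "rs2", "rs3"]
    z = [np.array([5.4, 1.0, 0.2]), np.array([4.8, 0.5, -0.3])]
    ld = [np.eye(3), np.eye(3)]
    return MultiStudyLocus(snp_ids, z, ld)
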