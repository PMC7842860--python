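import numpy as np
import pytest

import mtwopart as mt


@pytest.fixture(scope="session")
def reference():
    """Canonical 6-cluster x 30 LN fixture with its generating parameters."""
    data, truth = mt.make_reference_fixture()
    return data, truth


@pytest.fixture(scope="session")
def reference_spec():
    return mt.ModelSpec(family="LN", zero_covariates=("x1",), cont_covariates=("x1",))


@pytest.fixture(scope="session")
def small_block(reference):
    """A 5-observation block cut from the reference fixture."""
    data, _ = reference
    blk = data.cluster_blocks()[0]
    return mt.ClusterBlock(blk.cluster_id, blk.y[:5], blk.Z[:5], blk.X[:5])


@pytest.fixture(scope="session")
def reference_mtp_fit(reference, reference_spec):
    """One mTP-LN fit of the reference fixture, shared across tests."""
    data, _ = reference
    return mt.fit_mtp(data, reference_spec, mt.FitOptions(quad_order=10))


def assert_within_ses(estimates, truth, se, k=3.0):
    z = np.abs((np.asarray(estimates) - np.asarray(truth)) / np.asarray(se))
    assert np.all(z < k), f"|z| = {np.round(z, 2)} exceeds {k}"
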