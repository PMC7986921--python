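import numpy as np
import pytest

import trigsar as ts
from trigsar import qmodel


@pytest.fixture
def two_channel_q():
    """Closed-form 2-channel instance: SAR(phi) = 2 + cos(phi2 - phi1 + pi/2)
    for unit amplitudes; maximum 3 at phase difference -pi/2."""
    return np.array([[1.0, 0.5j], [-0.5j, 1.0]])


@pytest.fixture
def rank1_q():
    """Rank-1 matrix q q-dagger with q = (1, i); lambda_max = 2."""
    q = np.array([1.0, 1.0j])
    return np.outer(q, q.conj())


def random_psd(nc, rank, seed, decay=0.3):
    """Standalone seeded PSD matrix of bounded rank (independent of synth)."""
    rng = np.random.default_rng(seed)
    q = np.zeros((nc, nc), dtype=complex)
    for i in range(rank):
        v = (rng.standard_normal(nc) + 1j * rng.standard_normal(nc)) / np.sqrt(2)
        q += decay**i * np.outer(v.conj(), v)
    return q


@pytest.fixture(scope="session")
def phantom_pipeline():
    """Default phantom -> raw Q -> 10g-averaged Q, shared across tests."""
    fields = ts.generate_phantom_fields(ts.PhantomSpec())
    qraw = qmodel.build_q_field(fields)
    q10 = qmodel.average_10g(qraw, fields.grid)
    return fields, qraw, q10


@pytest.fixture(scope="session")
def hot_qset(phantom_pipeline):
    """The 200 highest-eigenvalue 10g-averaged matrices (peak region)."""
    _, _, q10 = phantom_pipeline
    lam = q10.max_eigenvalues()
    order = np.argsort(lam)[-200:]
    return ts.QMatrixSet(
        entries=q10.entries[order], voxel_index=q10.voxel_index[order], averaged=True
    )
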