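import numpy as np
import pytest

from bgpseq.encoder import desk_config
from bgpseq.synthetic_ehr import CohortSpec, generate_cohort
from bgpseq.train_infer import HeadConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """192 patients, short sequences — shared across training smoke tests."""
    spec = CohortSpec(n_patients=192, n_visits_range=(2, 4),
                      codes_per_visit_range=(2, 3), vocab_size=40,
                      risk_tokens={5: 2.5, 6: 1.5}, seed=11)
    records, truth, vocab = generate_cohort(spec)
    return spec, records, truth, vocab


@pytest.fixture
def tiny_encoder_config():
    return desk_config(vocab_size=40, pooled_size=4, hidden_size=16,
                       n_layers=1, n_heads=2, intermediate_size=32,
                       max_seq_len=32, max_positions=16, dropout=0.1)


@pytest.fixture
def tiny_head_config():
    return HeadConfig(n_inducing=8, grid_size=8)


def fd_gradient(f, param, eps=1e-6, indices=None):
    """Central finite-difference gradient of scalar f() w.r.t. param entries."""
    flat = param.data.ravel()
    if indices is None:
        indices = range(flat.size)
    grads = {}
    for j in indices:
        old = flat[j]
        flat[j] = old + eps
        fp = f().item()
        flat[j] = old - eps
        fm = f().item()
        flat[j] = old
        grads[j] = (fp - fm) / (2.0 * eps)
    return grads
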