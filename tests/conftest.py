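import numpy as np
import pytest

from dsmlink.dsm import TrainConfig, train_dsm
from dsmlink.hmm import HaplotypePanel, HMMParams, Haplotype, SiteEvidence
from dsmlink.simulate import SimConfig, make_linking_fixture


def random_instance(rng, K=None, V=None, with_evidence=True):
    """A random small chain instance for oracle comparisons."""
    K = K or int(rng.integers(1, 5))
    V = V or int(rng.integers(2, 7))
    panel = HaplotypePanel(
        rng.integers(0, 2, (K, V)),
        [f"v{i}" for i in range(V)],
        np.arange(V, dtype=np.int64) + 1,
        np.sort(rng.random(V)),
    )
    params = HMMParams(rng.random(V - 1), float(rng.uniform(0.01, 0.4)), np.full(K, 1 / K))
    h = Haplotype(rng.integers(0, 2, V))
    evidence = None
    if with_evidence:
        evidence = SiteEvidence(rng.random(V) + 0.05, rng.random(V) + 0.05)
    return panel, params, h, evidence


@pytest.fixture(scope="session")
def default_fixture():
    """The standard desk-scale linking experiment (shared across tests)."""
    return make_linking_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def trained_dsm(default_fixture):
    fx = default_fixture
    cfg = TrainConfig(
        recomb_scale=fx.config.recomb_scale, emission_error=fx.config.copy_error
    )
    return train_dsm(fx.train_pairs, fx.panel, fx.eqtl_map, cfg)


@pytest.fixture(scope="session")
def tiny_fixture():
    """A small fixture where brute-force path enumeration is feasible."""
    cfg = SimConfig(
        K_panel=3, V_sites=5, n_eqtls=3, genes_per_eqtl=2, n_noise_genes=2,
        ld_block_size=2, seed=5,
    )
    return make_linking_fixture(cfg, n_train=10, n_test=3, n_decoys=0)
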