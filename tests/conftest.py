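"""Shared fixtures: one default-scale simulation and its fitted model are
computed once per session and reused by the unit, property and acceptance
tests."""

import numpy as np
import pytest

from ovisepi import bsr_enhancers as bsr
from ovisepi import chromatin_states as cs
from ovisepi import expression as ex
from ovisepi.synthetic_epigenome import SimulationConfig, simulate

#: fixed session seed for the default-conditions dataset
SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_sim():
    """Dataset + truth at the generator's default study conditions."""
    return simulate(SimulationConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def dataset(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def truth(default_sim):
    return default_sim[1]


@pytest.fixture(scope="session")
def fitted_model(dataset):
    hmm = cs.BernoulliHMM(n_states=15, seed=0, max_iter=100, tol=1e-3)
    return hmm.fit(list(dataset.marks.values()))


@pytest.fixture(scope="session")
def replicate_segs(dataset, fitted_model):
    return {s: cs.decode(fitted_model, m) for s, m in dataset.marks.items()}


@pytest.fixture(scope="session")
def consensus_set(replicate_segs):
    enha = {s: seg.state_intervals("EnhA")
            for s, seg in replicate_segs.items()}
    return bsr.build_consensus(enha)


@pytest.fixture(scope="session")
def de_result(dataset):
    return ex.differential_expression(dataset.counts, dataset.sample_breeds,
                                      tpm_matrix=dataset.tpm)


def small_config(**overrides) -> SimulationConfig:
    """A reduced design for fast determinism/pipeline tests."""
    defaults = dict(seed=3, n_chroms=1, chrom_length=1_000_000, n_genes=50,
                    n_planted_deg=10, n_bsr_sh=6, n_bsr_hu=3, n_loops=4,
                    reads_per_library=2_000, generate_sequence=False)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
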