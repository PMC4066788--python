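"""Shared fixtures: one small simulated dataset reused across modules.

Everything is generated at test time from fixed seeds; nothing is read
from disk.
"""

import pytest

from imprintseq.simulate import (
    SimConfig,
    gen_endosperm_reads,
    gen_parental_reads,
    make_truth,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7, n_scaffolds=2, scaffold_len=60_000, n_genes=20, coverage_rna=50)


@pytest.fixture(scope="session")
def truth(sim_config):
    return make_truth(sim_config)


@pytest.fixture(scope="session")
def genome(truth):
    return truth.haplotypes["p1"]


@pytest.fixture(scope="session")
def parental_reads(sim_config, truth):
    return {p: gen_parental_reads(sim_config, p, truth) for p in ("p1", "p2")}


@pytest.fixture(scope="session")
def endosperm_reads(sim_config, truth):
    return {c: gen_endosperm_reads(sim_config, c, truth) for c in ("AxB", "BxA")}
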