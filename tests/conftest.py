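"""Shared simulation fixtures (session-scoped: each sim is built once)."""

from __future__ import annotations

import pytest

from nanomei import simforge
from nanomei.simforge import FamilyConfig, SimConfig


def small_l1_config(seed: int, error_free: bool = True, **nonref_kwargs) -> SimConfig:
    """A compact L1Hs-only design with spacious loci (no read cross-talk)."""
    config = SimConfig(
        seed=seed,
        genome_len=1_200_000,
        families=(
            FamilyConfig("L1Hs", 12, min_len=400, max_len=1500),
            FamilyConfig("L1PA2", 4, divergence=0.03, min_len=400, max_len=1500),
        ),
    )
    config.nonref.count = 10
    config.nonref.full_length_prob = 0.0
    config.nonref.max_len = 1500
    config.reads.reads_per_cut = 8.0
    config.reads.poisson = False
    if error_free:
        config.reads.sub_rate = config.reads.ins_rate = config.reads.del_rate = 0.0
    for k, v in nonref_kwargs.items():
        setattr(config.nonref, k, v)
    return config


def build(config: SimConfig):
    truth = simforge.implant_nonreference(simforge.build_reference(config))
    run = simforge.simulate_cas9_run(truth, simforge.toy_guide(config.nonref.subfamily))
    return truth, run


@pytest.fixture(scope="session")
def toy_lib():
    return simforge.toy_consensus_library()


@pytest.fixture(scope="session")
def clean_run():
    """Error-free enrichment run: 10 implants, 8 reads per cut site,
    elements long enough that every cut read leaves caller-visible evidence."""
    return build(small_l1_config(11, error_free=True, min_len=700))


@pytest.fixture(scope="session")
def noisy_run():
    """Same design under the default 3%/2%/2% error model."""
    return build(small_l1_config(13, error_free=False, min_len=700))


@pytest.fixture(scope="session")
def wgs_run():
    """Uniform-coverage (20x) error-free run over a smaller donor, for
    hallmark-exactness and genotyping checks."""
    config = SimConfig(
        seed=17,
        genome_len=400_000,
        families=(FamilyConfig("L1Hs", 4, min_len=400, max_len=1200),),
    )
    config.nonref.count = 8
    config.nonref.het_fraction = 0.5
    config.nonref.full_length_prob = 0.0
    config.nonref.max_len = 1500
    config.reads.sub_rate = config.reads.ins_rate = config.reads.del_rate = 0.0
    truth = simforge.implant_nonreference(simforge.build_reference(config))
    run = simforge.simulate_wgs_run(truth, depth=20.0)
    return truth, run
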