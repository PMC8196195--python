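"""Prepackaged simulation experiments.

Each experiment fixes a study design (genome scale, locus counts, read
model) and reports the quantity it was built to measure.  They are used
by the test suite and the reproduction script; all randomness derives
from the caller-supplied seed.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from . import simforge
from .analysis import depth_ratio
from .meicaller import CallerParams
from .pipeline import RunResult, run_pipeline

__all__ = ["ZygosityDepthResult", "zygosity_depth_ratio_experiment", "build_l1hs_run"]


def _l1hs_config(
    seed: int,
    genome_len: int = 2_400_000,
    n_ref: int = 30,
    n_nonref: int = 30,
    het_fraction: float = 1.0,
    reads_per_cut: float = 10.0,
    error_free: bool = False,
) -> simforge.SimConfig:
    config = simforge.SimConfig(
        seed=seed,
        genome_len=genome_len,
        families=(
            simforge.FamilyConfig("L1Hs", n_ref, min_len=400, max_len=1500),
            simforge.FamilyConfig("L1PA2", 6, divergence=0.03, min_len=400, max_len=1500),
        ),
    )
    config.nonref.count = n_nonref
    config.nonref.het_fraction = het_fraction
    config.nonref.full_length_prob = 0.0
    config.nonref.max_len = 1500
    config.reads.reads_per_cut = reads_per_cut
    if error_free:
        config.reads.sub_rate = config.reads.ins_rate = config.reads.del_rate = 0.0
    return config


def build_l1hs_run(seed: int, **kwargs) -> tuple[simforge.TruthSet, simforge.SimRun]:
    """One L1Hs enrichment run on a synthetic diploid donor."""
    config = _l1hs_config(seed, **kwargs)
    truth = simforge.implant_nonreference(simforge.build_reference(config))
    run = simforge.simulate_cas9_run(truth, simforge.toy_guide("L1Hs"))
    return truth, run


@dataclass
class ZygosityDepthResult:
    ratio: float              # mean over seeds of per-seed support ratios
    per_seed: list[float]
    n_ref_loci: int
    n_nonref_calls: int


def zygosity_depth_ratio_experiment(
    seed: int,
    n_seeds: int = 5,
    params: CallerParams = CallerParams(),
) -> ZygosityDepthResult:
    """Supporting-read depth at homozygous reference L1Hs loci versus
    heterozygous non-reference insertions, equal per-haplotype capture.

    Reference elements sit on both haplotypes (two cut sites), while each
    heterozygous insertion is cut on one, so the expected ratio of mean
    supporting reads is 2:1.  The experiment simulates one enrichment run
    per derived seed, classifies and calls it, and averages the per-run
    ratio of mean on-target-reference support to mean non-reference call
    support.
    """
    ratios = []
    n_ref = n_calls = 0
    for i in range(n_seeds):
        truth, run = build_l1hs_run(seed * 1000 + i)
        lib = list(truth.consensus.values())
        res: RunResult = run_pipeline(
            run.reads, run.alignments, truth.features, lib, "L1Hs",
            truth.genome, params=params, scan=False,
        )
        ref_supports = list(res.ref_support.values())
        nonref_supports = [c.support for c in res.nonref_calls]
        ratios.append(depth_ratio(ref_supports, nonref_supports))
        n_ref += len(ref_supports)
        n_calls += len(nonref_supports)
    return ZygosityDepthResult(statistics.mean(ratios), ratios, n_ref, n_calls)
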