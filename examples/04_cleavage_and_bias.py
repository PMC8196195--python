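"""Cleavage-site distribution and strand bias of a simulated run.

Aligns the first 80 bp of each cut read to the element consensus
(start-at-first-base, score >= 100) and bins the 5' ends by base distance
from the PAM NGG; also reports the forward/reverse read ratio.
"""

from nanomei.analysis import cleavage_site_histogram, strand_bias
from nanomei.simforge import (
    SimConfig, FamilyConfig, TOY_GUIDE_SITES, build_reference,
    implant_nonreference, simulate_cas9_run, toy_guide,
)

config = SimConfig(seed=19, genome_len=300_000,
                   families=(FamilyConfig("L1Hs", 6, min_len=500, max_len=1500),))
config.nonref.count = 6
config.nonref.full_length_prob = 0.0
config.nonref.max_len = 1500
config.reads.sub_rate = config.reads.ins_rate = config.reads.del_rate = 0.0

truth = implant_nonreference(build_reference(config))
run = simulate_cas9_run(truth, toy_guide("L1Hs"))

cut_ids = {p.read_id for p in run.provenance if p.frame in ("fwd", "rev")}
reads = [r for r in run.reads if r.id in cut_ids]
cons = truth.consensus["L1Hs"]
hist = cleavage_site_histogram(reads, cons, pam_pos=TOY_GUIDE_SITES["L1Hs"] + 20)

print("forward-strand cut distances from PAM:", dict(sorted(hist.forward.items())))
print("reverse-strand cut distances from PAM:", dict(sorted(hist.reverse.items())))
print("excluded:", hist.excluded or "none")

frames = [p.frame for p in run.provenance if p.frame in ("fwd", "rev")]
print(f"strand bias (fwd/rev): {strand_bias(frames):.2f} (configured 4.6)")

# Forward reads start 3-4 bases from the PAM, reverse reads at 7 — the
# cut-offset model — and the forward excess reflects Cas9 staying bound
# on one side of the cut after cleavage.
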