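"""Design subfamily-specific guides for an AluYb8-like target.

Builds a small synthetic genome carrying Alu copies, finds consensus
positions that distinguish AluYb8 from its AluY/AluYa5 outgroups, and
prints the top-ranked 23-mer guide candidates (20 bp protospacer + NGG
PAM) with their tiers.
"""

import numpy as np

from nanomei.guide_design import design_guides
from nanomei.seqio import SequenceRecord
from nanomei.simforge import toy_consensus_library

lib = toy_consensus_library()
target = lib["AluYb8"]
outgroups = [lib["AluY"], lib["AluYa5"]]

# a toy genome with ten AluYb8 copies in random background
rng = np.random.default_rng(0)
background = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
genome = SequenceRecord("toy", background[:25_000] + target.seq * 10 + background[25_000:])

ranked = design_guides(target, outgroups, [genome], target_copy_count=10)
print(f"{len(ranked)} candidates; top five:")
print("pos23  pam_side         n_diag  pam_diag  genome_freq  tier")
for c in ranked[:5]:
    print(f"{c.consensus_pos:5d}  {c.pam_side:15s}  {len(c.diagnostic_hits):5d}  "
          f"{str(c.diag_in_pam_GGCC):8s}  {c.genome_freq:10d}  {c.tier}")

# Tier0 = a subfamily-diagnostic base sits on a PAM G/C, the ideal case;
# genome_freq near the copy number means the guide is subfamily-unique.
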