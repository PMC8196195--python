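"""Subfamily-specific guide RNA design and theoretical capture bounds.

A guide is a 23-mer (20 bp protospacer + NGG PAM, or the reverse-strand
CCN layout) drawn from a target subfamily consensus.  Diagnostic positions
are consensus columns where the target base differs from *every* outgroup
base; candidates must contain at least one.  Candidates are tiered by
where their diagnostic bases fall and how often the 23-mer occurs in the
reference genome, then ranked toward the element 3' end, next to the
poly(A) tract that target-primed reverse transcription requires.

Capture bounds classify how well a chosen guide matches an element copy:

* ``lower``        exact 23/23 match somewhere in the element,
* ``intermediate`` best placement within 3 mismatches or gaps,
* ``upper``        at least 14 of the 23 guide bases (>60%) aligned as
  identical in the best-scoring semi-global placement,

nested so that count(lower) <= count(intermediate) <= count(upper).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import make_aligner, semiglobal_best_matches, edit_distance_semiglobal
from .seqio import RepeatFeature, SequenceRecord, revcomp

__all__ = [
    "DiagnosticProfile",
    "GuideCandidate",
    "BoundSummary",
    "diagnostic_positions",
    "enumerate_guide_candidates",
    "count_kmer_frequency",
    "genome_frequency",
    "assign_tier",
    "rank_guides",
    "classify_guide_match",
    "compute_capture_bounds",
    "design_guides",
]

K = 23
BOUND_ORDER = ("lower", "intermediate", "upper")
LOWER_EXACT = 23        # perfect protospacer+PAM match
INTERMEDIATE_MAX_EDITS = 3   # <=3 bp mismatch or gap
UPPER_MIN_MATCHES = 14  # >60% of 23 bp


@dataclass
class DiagnosticProfile:
    target_id: str
    outgroup_ids: tuple[str, ...]
    positions: tuple[int, ...]  # 0-based on the ungapped target consensus


@dataclass
class GuideCandidate:
    seq23: str
    pam_side: str                      # three_prime_NGG | five_prime_CCN
    consensus_pos: int                 # 0-based start on the target consensus
    diagnostic_hits: tuple[int, ...]   # offsets 0..22 within the 23-mer
    diag_in_pam_GGCC: bool
    genome_freq: int = -1
    tier: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq23) != K:
            raise ValueError("guide candidates are 23-mers")
        if self.pam_side == "three_prime_NGG" and self.seq23[21:23] != "GG":
            raise ValueError("3' PAM candidate must end in GG")
        if self.pam_side == "five_prime_CCN" and self.seq23[0:2] != "CC":
            raise ValueError("5' PAM candidate must start with CC")


def _seq_of(x) -> str:
    return x.seq if isinstance(x, SequenceRecord) else str(x)


def _id_of(x, default: str) -> str:
    return x.id if isinstance(x, SequenceRecord) else default


_msa_aligner = None


def _project_to_target(target: str, other: str) -> list[str]:
    """Per-target-position base of `other` after global alignment ('-' = gap)."""
    global _msa_aligner
    if _msa_aligner is None:
        _msa_aligner = make_aligner(1, -1, -2, -2, "global")
    aln = _msa_aligner.align(target, other)[0]
    column = ["-"] * len(target)
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for i in range(te - ts):
            column[ts + i] = other[qs + i]
    return column


def diagnostic_positions(target, outgroups: Sequence, aligned: bool = False) -> DiagnosticProfile:
    """Consensus positions where the target differs from every outgroup.

    With ``aligned=True`` the inputs are rows of one alignment (may contain
    ``-``); positions are reported on the ungapped target.  Otherwise each
    outgroup is anchored to the target by the packaged progressive pairwise
    aligner (match 1 / mismatch -1 / gap -2).  A gap or N in any outgroup
    disqualifies the column, as does a non-ACGT target base.
    """
    if not outgroups:
        raise ValueError("diagnosticity is undefined without outgroups")
    tseq = _seq_of(target)
    oseqs = [_seq_of(o) for o in outgroups]
    if aligned:
        if any(len(o) != len(tseq) for o in oseqs):
            raise ValueError("aligned=True requires equal-length rows")
        positions = []
        tpos = 0
        for col in range(len(tseq)):
            tb = tseq[col]
            if tb == "-":
                continue
            if tb in "ACGT" and all(o[col] in "ACGT" and o[col] != tb for o in oseqs):
                positions.append(tpos)
            tpos += 1
        return DiagnosticProfile(
            _id_of(target, "target"), tuple(_id_of(o, f"out{i}") for i, o in enumerate(outgroups)), tuple(positions)
        )
    columns = [_project_to_target(tseq, o) for o in oseqs]
    positions = [
        i
        for i, tb in enumerate(tseq)
        if tb in "ACGT" and all(c[i] in "ACGT" and c[i] != tb for c in columns)
    ]
    return DiagnosticProfile(
        _id_of(target, "target"), tuple(_id_of(o, f"out{i}") for i, o in enumerate(outgroups)), tuple(positions)
    )


def enumerate_guide_candidates(target, profile: DiagnosticProfile, k: int = K) -> list[GuideCandidate]:
    """All PAM-bearing 23-mer windows containing a diagnostic position."""
    if k != K:
        raise ValueError("only k=23 guides are supported")
    seq = _seq_of(target)
    diag = set(profile.positions)
    out: list[GuideCandidate] = []
    for start in range(0, len(seq) - k + 1):
        window = seq[start : start + k]
        if "N" in window:
            continue
        hits = tuple(p - start for p in sorted(diag) if start <= p < start + k)
        if not hits:
            continue
        if window[21:23] == "GG":
            out.append(
                GuideCandidate(
                    window, "three_prime_NGG", start, hits,
                    diag_in_pam_GGCC=any(h in (21, 22) for h in hits),
                )
            )
        if window[0:2] == "CC":
            out.append(
                GuideCandidate(
                    window, "five_prime_CCN", start, hits,
                    diag_in_pam_GGCC=any(h in (0, 1) for h in hits),
                )
            )
    return out


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1  # overlapping occurrences count


def count_kmer_frequency(
    genome: Sequence[SequenceRecord] | SequenceRecord,
    kmers: Sequence[str],
    pam_substitution: bool = False,
    n_index: Optional[int] = None,
    both_strands: bool = True,
) -> dict[str, int]:
    """Occurrences of each k-mer in the genome (overlapping, both strands).

    With ``pam_substitution`` the base at ``n_index`` (the N of the PAM) is
    expanded to all four bases and the counts summed.
    """
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    if not records:
        raise ValueError("empty genome")
    if kmers and len({len(k) for k in kmers}) > 1:
        raise ValueError("k-mers must share one length")
    if pam_substitution and n_index is None:
        raise ValueError("pam_substitution requires n_index")
    counts: dict[str, int] = {}
    texts = [r.seq for r in records]
    for kmer in kmers:
        if "N" in kmer:
            raise ValueError(f"k-mer {kmer!r} contains N")
        variants = [kmer]
        if pam_substitution:
            variants = [kmer[:n_index] + b + kmer[n_index + 1 :] for b in "ACGT"]
        total = 0
        for v in set(variants):
            for text in texts:
                total += _count_occurrences(text, v)
                if both_strands:
                    total += _count_occurrences(text, revcomp(v))
        counts[kmer] = total
    return counts


def genome_frequency(genome, cands: Iterable[GuideCandidate], pam_substitution: bool = True) -> None:
    """Fill ``genome_freq`` for each candidate (N-of-PAM expanded)."""
    for c in cands:
        n_index = 20 if c.pam_side == "three_prime_NGG" else 2
        c.genome_freq = count_kmer_frequency(
            genome, [c.seq23], pam_substitution=pam_substitution, n_index=n_index
        )[c.seq23]


def assign_tier(cand: GuideCandidate, target_copy_count: int) -> str:
    """Tier0: diagnostic base on a PAM G/C; Tier1: genome frequency below
    twice the target copy count; Tier2: otherwise."""
    if target_copy_count <= 0:
        raise ValueError("target_copy_count must be positive")
    if cand.genome_freq < 0:
        raise ValueError("genome_freq not populated")
    if cand.diag_in_pam_GGCC:
        cand.tier = "Tier0"
    elif cand.genome_freq < 2 * target_copy_count:
        cand.tier = "Tier1"
    else:
        cand.tier = "Tier2"
    return cand.tier


def rank_guides(cands: Sequence[GuideCandidate], consensus_len: Optional[int] = None) -> list[GuideCandidate]:
    """Stable sort: tier, then diagnostic count (desc), then 3'-proximity."""
    if not cands:
        raise ValueError("no candidates to rank")
    if consensus_len is None:
        consensus_len = max(c.consensus_pos + K for c in cands)
    order = {"Tier0": 0, "Tier1": 1, "Tier2": 2, None: 3}
    return sorted(
        cands,
        key=lambda c: (
            order.get(c.tier, 3),
            -len(c.diagnostic_hits),
            consensus_len - (c.consensus_pos + K),
            c.consensus_pos,
        ),
    )


def classify_guide_match(guide: str, element_seq: str) -> str:
    """Capture-bound class of one guide against one element (both strands)."""
    if len(guide) != K:
        raise ValueError("guide must be 23 bp")
    if len(element_seq) < UPPER_MIN_MATCHES:
        return "none"
    targets = (element_seq, revcomp(element_seq))
    if any(guide in t for t in targets):
        return "lower"
    dists = [
        d
        for d in (edit_distance_semiglobal(guide, t, INTERMEDIATE_MAX_EDITS) for t in targets)
        if d >= 0  # edlib reports -1 when the bound is exceeded
    ]
    if dists and min(dists) <= INTERMEDIATE_MAX_EDITS:
        return "intermediate"
    if max(semiglobal_best_matches(guide, t)[1] for t in targets) >= UPPER_MIN_MATCHES:
        return "upper"
    return "none"


@dataclass
class BoundSummary:
    """Cumulative per-subfamily, per-status counts of the nested classes."""

    counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def add(self, subfamily: str, status: str, bound: str) -> None:
        row = self.counts.setdefault((subfamily, status), {b: 0 for b in BOUND_ORDER})
        if bound == "none":
            return
        reached = BOUND_ORDER.index(bound)
        for b in BOUND_ORDER[reached:]:
            row[b] += 1

    def get(self, subfamily: str, status: str) -> dict[str, int]:
        return self.counts.get((subfamily, status), {b: 0 for b in BOUND_ORDER})


def compute_capture_bounds(
    guide: str,
    genome: SequenceRecord,
    ref_elements: Sequence[RepeatFeature],
    nonref_elements: Sequence[SequenceRecord] = (),
    nonref_subfamily: str = "",
) -> BoundSummary:
    """Per-subfamily counts of reference and non-reference elements in each
    nested capture class for one guide."""
    summary = BoundSummary()
    for feat in ref_elements:
        if feat.ref_name != genome.id:
            continue
        if feat.end > len(genome.seq):
            raise ValueError(f"feature {feat.subfamily}@{feat.start} outside genome bounds")
        el = genome.seq[feat.start : feat.end]
        summary.add(feat.subfamily, "reference", classify_guide_match(guide, el))
    for rec in nonref_elements:
        summary.add(nonref_subfamily or rec.id, "non_reference", classify_guide_match(guide, rec.seq))
    return summary


def design_guides(
    target: SequenceRecord,
    outgroups: Sequence[SequenceRecord],
    genome,
    target_copy_count: int,
    aligned: bool = False,
) -> list[GuideCandidate]:
    """End-to-end candidate design: diagnostics, enumeration, tiering, ranking."""
    profile = diagnostic_positions(target, outgroups, aligned=aligned)
    cands = enumerate_guide_candidates(target, profile)
    if not cands:
        return []
    genome_frequency(genome, cands)
    for c in cands:
        assign_tier(c, target_copy_count)
    return rank_guides(cands, consensus_len=len(target.seq))
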