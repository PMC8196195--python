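"""Downstream analyses of Cas9-enrichment runs.

Cleavage-site distributions around the PAM, strand bias, saturation of
call recovery under cumulative run merging, trio transmission of
non-reference insertions, depth ratios, fold enrichment over a
whole-genome baseline, and recurrence (dot) plots.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Sequence

from .align import make_aligner
from .meicaller import InsertionSignal, MEICallRecord, cluster_supporting_reads
from .seqio import QualityRead, SequenceRecord, family_of, revcomp

__all__ = [
    "CleavageHistogram",
    "SaturationPoint",
    "TransmissionRecord",
    "RunCallData",
    "cleavage_site_histogram",
    "strand_bias",
    "saturation_curve",
    "trio_transmission",
    "depth_ratio",
    "fold_enrichment",
    "recurrence_matrix",
]


# ---------------------------------------------------------------------------
# Cleavage sites
# ---------------------------------------------------------------------------

@dataclass
class CleavageHistogram:
    """Per-strand read counts by base distance from the PAM NGG."""

    forward: dict[int, int] = field(default_factory=dict)
    reverse: dict[int, int] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return sum(self.forward.values()) + sum(self.reverse.values())

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


def cleavage_site_histogram(
    reads: Sequence[QualityRead],
    consensus: SequenceRecord,
    pam_pos: int,
    head_bp: int = 80,
    gap_open: float = -10.0,
    gap_extend: float = -5.0,
    match: float = 2.0,
    mismatch: float = -1.0,
    min_score: float = 100.0,
) -> CleavageHistogram:
    """Cut-site distribution from read heads aligned to the consensus.

    Only the first ``head_bp`` bases of each read are aligned, against the
    consensus and its reverse complement; an included read must align from
    its very first base and score at least ``min_score``.  Each included
    read contributes its 5'-end distance from the PAM N (``pam_pos``) to
    the strand-appropriate bin.
    """
    if not (0 <= pam_pos < len(consensus.seq)):
        raise ValueError("PAM position outside the consensus")
    aligner = make_aligner(match, mismatch, gap_open, gap_extend, "local")
    cons_f = consensus.seq
    cons_r = revcomp(cons_f)
    hist = CleavageHistogram()
    for read in reads:
        head = read.seq[:head_bp]
        best = None  # (score, strand, target_start_of_read_base0)
        for strand, target in (("+", cons_f), ("-", cons_r)):
            alns = aligner.align(target, head)
            try:
                a = alns[0]
            except IndexError:
                continue
            score = float(a.score)
            if best is None or score > best[0]:
                tb, qb = a.aligned
                best = (score, strand, int(tb[0][0]), int(qb[0][0]))
        if best is None or best[0] < min_score:
            hist.excluded["min_score"] = hist.excluded.get("min_score", 0) + 1
            continue
        score, strand, tstart, qstart = best
        if qstart != 0:
            hist.excluded["not_first_base"] = hist.excluded.get("not_first_base", 0) + 1
            continue
        if strand == "+":
            pos = tstart
            bins = hist.forward
        else:
            pos = len(cons_f) - 1 - tstart
            bins = hist.reverse
        d = pam_pos - pos
        bins[d] = bins.get(d, 0) + 1
    return hist


def strand_bias(strands: Sequence[str]) -> float:
    """Forward/reverse read ratio; infinity when no reverse reads."""
    fwd = sum(1 for s in strands if s in ("+", "fwd"))
    rev = sum(1 for s in strands if s in ("-", "rev"))
    if fwd + rev == 0:
        raise ValueError("no stranded reads")
    if rev == 0:
        return math.inf
    return fwd / rev


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

@dataclass
class RunCallData:
    """One flow cell's contribution to saturation: its on-target read count
    and the per-read insertion signals it produced."""

    run_id: str
    on_target_reads: int
    signals: list[InsertionSignal]


@dataclass
class SaturationPoint:
    runs_merged: int
    cumulative_on_target_reads: int
    calls_recovered: dict[int, int]  # supporting-read cutoff -> n calls


def saturation_curve(
    runs: Sequence[RunCallData],
    cutoffs: Sequence[int] = (1, 4, 15),
    cluster_window: int = 100,
) -> list[SaturationPoint]:
    """Re-call the cumulative union of runs, best-ranked first.

    Runs are ranked by on-target read count (descending) and merged one at
    a time; after each merge the pooled signals are re-clustered and the
    number of clusters meeting each supporting-read cutoff is recorded.
    """
    if not runs:
        raise ValueError("no runs to merge")
    ranked = sorted(runs, key=lambda r: -r.on_target_reads)
    merged: list[InsertionSignal] = []
    total = 0
    points: list[SaturationPoint] = []
    for i, run in enumerate(ranked, 1):
        merged.extend(run.signals)
        total += run.on_target_reads
        calls = {
            c: len(cluster_supporting_reads(merged, cluster_window, c)) for c in cutoffs
        }
        points.append(SaturationPoint(i, total, calls))
    return points


# ---------------------------------------------------------------------------
# Trio transmission
# ---------------------------------------------------------------------------

@dataclass
class TransmissionRecord:
    call: MEICallRecord
    category: str  # from_parent1 | from_parent2 | either_parent | unmatched | untransmitted_parent_call
    origin: str    # child | parent1 | parent2


def _match(a: MEICallRecord, b: MEICallRecord, window: int) -> bool:
    return (
        a.ref_name == b.ref_name
        and abs(a.position - b.position) <= window
        and (a.subfamily == b.subfamily or family_of(a.subfamily) == family_of(b.subfamily))
    )


def trio_transmission(
    child_calls: Sequence[MEICallRecord],
    parent1_calls: Sequence[MEICallRecord],
    parent2_calls: Sequence[MEICallRecord],
    match_window: int = 100,
) -> list[TransmissionRecord]:
    """Categorise child calls by parental origin and flag untransmitted
    parental calls (same reference, breakpoints within ``match_window``,
    subfamily agreement at least at the family level)."""
    records: list[TransmissionRecord] = []
    matched1: set[int] = set()
    matched2: set[int] = set()
    for c in child_calls:
        in1 = any(_match(c, p, match_window) for p in parent1_calls)
        in2 = any(_match(c, p, match_window) for p in parent2_calls)
        if in1:
            matched1.update(i for i, p in enumerate(parent1_calls) if _match(c, p, match_window))
        if in2:
            matched2.update(i for i, p in enumerate(parent2_calls) if _match(c, p, match_window))
        if in1 and in2:
            cat = "either_parent"
        elif in1:
            cat = "from_parent1"
        elif in2:
            cat = "from_parent2"
        else:
            cat = "unmatched"
        records.append(TransmissionRecord(c, cat, "child"))
    for i, p in enumerate(parent1_calls):
        if i not in matched1:
            records.append(TransmissionRecord(p, "untransmitted_parent_call", "parent1"))
    for i, p in enumerate(parent2_calls):
        if i not in matched2:
            records.append(TransmissionRecord(p, "untransmitted_parent_call", "parent2"))
    return records


def transmission_support_summary(records: Sequence[TransmissionRecord]) -> dict[str, float]:
    groups: dict[str, list[int]] = {}
    for r in records:
        groups.setdefault(r.category, []).append(r.call.support)
    return {k: float(statistics.mean(v)) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# Depth ratio and fold enrichment
# ---------------------------------------------------------------------------

def depth_ratio(
    calls_reference: Sequence[MEICallRecord] | Sequence[int],
    calls_nonreference: Sequence[MEICallRecord] | Sequence[int],
) -> float:
    """Mean supporting-read depth at reference loci over non-reference loci.

    Homozygous reference elements sit on both haplotypes while many
    non-reference insertions are heterozygous, so with equal per-haplotype
    capture this ratio is expected near 2:1.
    """
    def supports(calls):
        vals = [c.support if isinstance(c, MEICallRecord) else int(c) for c in calls]
        if not vals:
            raise ValueError("empty call set")
        return vals

    return statistics.mean(supports(calls_reference)) / statistics.mean(supports(calls_nonreference))


def fold_enrichment(
    reads_per_target_capture: dict[str, float],
    reads_per_target_wgs: dict[str, float],
) -> dict[str, float]:
    """Per-subfamily ratio of average reads per element, capture vs WGS."""
    out = {}
    for sub, cap in reads_per_target_capture.items():
        wgs = reads_per_target_wgs.get(sub, 0.0)
        if wgs <= 0:
            raise ValueError(f"zero WGS denominator for {sub}")
        out[sub] = cap / wgs
    return out


# ---------------------------------------------------------------------------
# Recurrence (dot) plots
# ---------------------------------------------------------------------------

def recurrence_matrix(
    seq_a: str | SequenceRecord,
    seq_b: str | SequenceRecord,
    word: int = 10,
    mode: str = "forward",
) -> list[tuple[int, int]]:
    """(i, j) pairs where a length-``word`` segment of seq_a equals the
    corresponding segment of seq_b (or its reverse complement)."""
    a = seq_a.seq if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.seq if isinstance(seq_b, SequenceRecord) else seq_b
    if len(a) < word or len(b) < word:
        raise ValueError("sequences shorter than the word size")
    if mode not in ("forward", "revcomp"):
        raise ValueError("mode must be forward or revcomp")
    index: dict[str, list[int]] = {}
    for j in range(len(b) - word + 1):
        w = b[j : j + word]
        if mode == "revcomp":
            w = revcomp(w)
        if "N" not in w:
            index.setdefault(w, []).append(j)
    points: list[tuple[int, int]] = []
    for i in range(len(a) - word + 1):
        w = a[i : i + word]
        for j in index.get(w, ()):
            points.append((i, j))
    points.sort()
    return points
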