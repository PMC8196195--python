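"""Non-reference MEI calling from pre-masked long-read alignments.

Insertion evidence is taken from CIGAR insertions and terminal soft clips
that fall in unmasked portions of a read, assigned to a consensus
subfamily, and clustered by reference breakpoint.  Clusters with enough
supporting reads become calls annotated with the TPRT hallmarks: target
site duplication (TSD), poly(A) tract, L1 endonuclease cleavage-site
match (5'-TTTT/AA), 5' inversion (twin priming), 3' transduction, and an
empty-site check.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .align import best_local, scan_aligner
from .seqio import (
    AlignmentRecord,
    Hallmarks,
    MEICallRecord,
    QualityRead,
    RepeatFeature,
    SequenceRecord,
    family_of,
    revcomp,
)
from .readclass import MaskedRead, filter_reads, project_annotation_to_read

__all__ = [
    "CallerParams",
    "InsertionSignal",
    "CallCluster",
    "extract_insertion_signals",
    "assign_subfamily",
    "detect_tsd",
    "detect_polya",
    "detect_en_motif",
    "cluster_supporting_reads",
    "genotype_call",
    "apply_depth_filter",
    "call_nonreference",
]

EN_MOTIF = "TTTTAA"


@dataclass
class CallerParams:
    min_ins_len: int = 100
    min_clip_len: int = 200
    cluster_window: int = 100
    min_support: int = 4
    min_q: float = 7.0
    min_mapq: int = 10
    flank_window: int = 50
    min_tsd: int = 5
    max_tsd: int = 30
    tsd_max_mismatch: int = 1
    polya_min_len: int = 10
    polya_purity: float = 0.8
    polya_window: int = 20
    subfamily_min_score: float = 60.0
    hom_threshold: float = 0.8
    het_threshold: float = 0.2
    span_margin: int = 20
    transduction_min_len: int = 30
    max_masked_fraction: float = 0.5
    depth_filter: bool = False
    depth_bin: int = 500
    depth_max_fold: float = 2.0


@dataclass
class InsertionSignal:
    read_id: str
    ref_name: str
    breakpoint: int            # 0-based reference position
    source: str                # cigar_insertion | soft_clip
    ins_seq: str
    read_interval: tuple[int, int]   # original read coordinates
    flank5: str = ""           # reference window ending at the breakpoint
    flank3: str = ""           # reference window starting at the breakpoint
    clip_side: str = ""        # left | right (soft clips only)


@dataclass
class CallCluster:
    ref_name: str
    signals: list[InsertionSignal]
    position: int
    span_reads_total: int = 0
    call: Optional[MEICallRecord] = None

    @property
    def support(self) -> int:
        return len(self.signals)


# ---------------------------------------------------------------------------
# Signal extraction
# ---------------------------------------------------------------------------

def extract_insertion_signals(
    aln: AlignmentRecord,
    read_seq: str,
    masked: Optional[MaskedRead] = None,
    genome: Optional[SequenceRecord] = None,
    params: CallerParams = CallerParams(),
) -> list[InsertionSignal]:
    """CIGAR insertions >= min_ins_len and terminal clips >= min_clip_len,
    restricted to unmasked read intervals."""
    aligned = aln.aligned_read_seq(read_seq)
    W = params.flank_window
    sigs: list[InsertionSignal] = []
    qpos, rpos = 0, aln.ref_start
    n_ops = len(aln.cigar)
    for i, (op, n) in enumerate(aln.cigar):
        if op in "SH":
            is_left = i == 0
            is_right = i == n_ops - 1
            if op == "S" and n >= params.min_clip_len and (is_left or is_right):
                bp = aln.ref_start if is_left else aln.ref_end
                interval = (qpos, qpos + n)
                sigs.append(
                    InsertionSignal(
                        aln.read_id, aln.ref_name, bp, "soft_clip",
                        aligned[qpos : qpos + n], interval,
                        clip_side="left" if is_left else "right",
                    )
                )
            qpos += n if op == "S" else 0
        elif op == "I":
            if n >= params.min_ins_len:
                sigs.append(
                    InsertionSignal(
                        aln.read_id, aln.ref_name, rpos, "cigar_insertion",
                        aligned[qpos : qpos + n], (qpos, qpos + n),
                    )
                )
            qpos += n
        elif op in "M=X":
            qpos += n
            rpos += n
        elif op in "DN":
            rpos += n
    out = []
    for s in sigs:
        a, b = s.read_interval
        if aln.strand == "-":
            a, b = aln.read_len - b, aln.read_len - a
        s.read_interval = (a, b)
        if masked is not None and masked.masked_fraction(a, b) > params.max_masked_fraction:
            continue
        if genome is not None:
            g = genome.seq
            s.flank5 = g[max(0, s.breakpoint - W) : s.breakpoint]
            s.flank3 = g[s.breakpoint : s.breakpoint + W]
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Subfamily / strand / twin-priming assignment
# ---------------------------------------------------------------------------

def assign_subfamily(
    ins_seq: str,
    consensus_lib: Sequence[SequenceRecord],
    min_score: float = 60.0,
) -> tuple[str, str, str, bool]:
    """(family, subfamily, strand, inverted5) by best local consensus hit.

    ``inverted5`` flags the twin-priming signature: the 5' portion of the
    insertion aligning to the consensus in the orientation opposite to the
    3' portion.
    """
    if not ins_seq:
        raise ValueError("empty insertion sequence")
    aligner = scan_aligner()
    # long insertions are scored by their outer segments: the 3' end carries
    # the subfamily-diagnostic region next to the poly(A), the 5' end the
    # truncation point — interior sequence adds cost but no discrimination
    if len(ins_seq) > 800:
        probes = (ins_seq[:350], ins_seq[-450:])
    else:
        probes = (ins_seq,)
    # candidate selection by edit distance (fast), final score by the
    # local aligner against the winning consensus/strand only
    cand = None
    for cons in consensus_lib:
        for strand, t in (("+", cons.seq), ("-", revcomp(cons.seq))):
            d = sum(
                edlib.align(p, t, mode="HW", task="distance")["editDistance"] for p in probes
            )
            if cand is None or d < cand[0]:
                cand = (d, cons.id, strand)
    _, name, strand = cand
    cons_seq = next(c.seq for c in consensus_lib if c.id == name)
    t = cons_seq if strand == "+" else revcomp(cons_seq)
    score = sum(float(aligner.score(t, p)) for p in probes)
    if score < min_score:
        return "unknown", "unknown", "+", False
    inverted5 = False
    if len(ins_seq) >= 400:
        cons = next(c for c in consensus_lib if c.id == name)
        scores = {}
        for part, s in (("five", ins_seq[:350]), ("three", ins_seq[-350:])):
            fwd = float(aligner.score(cons.seq, s))
            rev = float(aligner.score(revcomp(cons.seq), s))
            scores[part] = ("+", fwd) if fwd >= rev else ("-", rev)
        (o5, s5), (o3, s3) = scores["five"], scores["three"]
        if s5 >= min_score and s3 >= min_score and o5 != o3:
            inverted5 = True
            strand = o3  # the 3' portion defines the element orientation
    return family_of(name), name, strand, inverted5


# ---------------------------------------------------------------------------
# Hallmarks
# ---------------------------------------------------------------------------

def _longest_junction_word(a: str, b: str, min_len: int, max_len: int, max_mismatch: int) -> str:
    """Longest prefix-anchored word shared by a and b, <=max_mismatch
    substitutions, first and last base matching exactly."""
    top = min(len(a), len(b), max_len)
    for L in range(top, min_len - 1, -1):
        if a[0] != b[0] or a[L - 1] != b[L - 1]:
            continue
        mm = sum(x != y or x == "N" for x, y in zip(a[:L], b[:L]))
        if mm <= max_mismatch:
            return a[:L]
    return ""


def detect_tsd(
    ins_seq: str,
    flank5: str,
    flank3: str,
    min_tsd: int = 5,
    max_tsd: int = 30,
    max_mismatch: int = 1,
) -> Optional[str]:
    """Target-site-duplication motif for one insertion signal.

    For a left-aligned insertion the duplicated word is simultaneously a
    prefix of the inserted sequence and of the reference downstream of the
    breakpoint; for a right-aligned insertion it is a suffix of both the
    inserted sequence and the upstream reference.  The longer qualifying
    word wins; ``None`` below ``min_tsd``.
    """
    cand1 = _longest_junction_word(ins_seq, flank3, min_tsd, max_tsd, max_mismatch)
    cand2 = _longest_junction_word(ins_seq[::-1], flank5[::-1], min_tsd, max_tsd, max_mismatch)[::-1]
    best = cand1 if len(cand1) >= len(cand2) else cand2
    return best or None


def detect_polya(seq: str, strand: str = "+", min_len: int = 10, purity: float = 0.8, window: int = 20) -> int:
    """Terminal poly(A) tract length (poly(T) at the 5' end for '-' calls).

    Walking inward from the element 3' terminus, the tract is the longest
    stretch that starts on an A and keeps every trailing length-``window``
    sub-window at A-fraction >= ``purity``; 0 below ``min_len``.
    """
    if not seq:
        return 0
    if strand == "-":
        # a minus-strand element shows its poly(A) as a 5' poly(T) tract
        return detect_polya(revcomp(seq), "+", min_len, purity, window)
    best = 0
    n = len(seq)
    for L in range(1, n + 1):
        seg = seq[n - L :]
        head = seg[: min(window, L)]  # the most recently scanned window
        if head.count("A") / len(head) < purity:
            break
        if seg[0] == "A":
            best = L
    return best if best >= min_len else 0


def detect_en_motif(window: str, break_index: Optional[int] = None) -> int:
    """Matches (0-6) of the breakpoint-spanning 6-mer to the L1
    endonuclease consensus 5'-TTTT/AA (four bases 5' of the nick, two 3')."""
    if len(window) < 6:
        raise ValueError("EN window must be at least 6 bp")
    if len(window) == 6 and break_index is None:
        six = window
    else:
        c = break_index if break_index is not None else len(window) // 2
        if c - 4 < 0 or c + 2 > len(window):
            raise ValueError("breakpoint too close to the window edge")
        six = window[c - 4 : c + 2]
    return sum(a == b for a, b in zip(six, EN_MOTIF))


# ---------------------------------------------------------------------------
# Clustering, genotyping, filtering
# ---------------------------------------------------------------------------

def cluster_supporting_reads(
    signals: Sequence[InsertionSignal],
    cluster_window: int = 100,
    min_support: int = 4,
) -> list[CallCluster]:
    """Single-linkage clustering of signals along the reference; one signal
    per read per cluster (the longest); clusters below min_support drop."""
    by_pos = sorted(signals, key=lambda s: (s.ref_name, s.breakpoint))
    raw: list[list[InsertionSignal]] = []
    for s in by_pos:
        if raw and raw[-1][0].ref_name == s.ref_name and s.breakpoint - raw[-1][-1].breakpoint <= cluster_window:
            raw[-1].append(s)
        else:
            raw.append([s])
    clusters: list[CallCluster] = []
    for group in raw:
        per_read: dict[str, InsertionSignal] = {}
        for s in group:
            old = per_read.get(s.read_id)
            if old is None or len(s.ins_seq) > len(old.ins_seq):
                per_read[s.read_id] = s
        members = sorted(per_read.values(), key=lambda s: s.breakpoint)
        if len(members) < min_support:
            continue
        pos = int(statistics.median(s.breakpoint for s in members))
        clusters.append(CallCluster(members[0].ref_name, members, pos))
    return clusters


def genotype_call(
    support: int,
    span_reads_total: int,
    hom_threshold: float = 0.8,
    het_threshold: float = 0.2,
) -> str:
    """Carrier-fraction genotype: hom above 0.8, het in [0.2, 0.8), else unknown."""
    if span_reads_total == 0:
        raise ValueError("span_reads_total must be positive")
    if span_reads_total < support:
        span_reads_total = support
    f = support / span_reads_total
    if f >= hom_threshold:
        return "hom"
    if f >= het_threshold:
        return "het"
    return "unknown"


def apply_depth_filter(
    position: int,
    coverage: Sequence[int],
    bin_bp: int = 500,
    max_fold: float = 2.0,
) -> tuple[bool, str]:
    """Empirical read-depth curation: the bin holding the insertion must stay
    within a factor of ``max_fold`` of the flanking-bin median (strict)."""
    b = position // bin_bp
    nbins = (len(coverage) + bin_bp - 1) // bin_bp

    def bin_depth(i: int) -> float:
        seg = coverage[i * bin_bp : (i + 1) * bin_bp]
        return float(sum(seg)) / max(1, len(seg))

    flanks = [bin_depth(i) for i in (b - 2, b - 1, b + 1, b + 2) if 0 <= i < nbins]
    if not flanks or statistics.median(flanks) == 0:
        return False, "no_flank_coverage"
    ratio = bin_depth(b) / statistics.median(flanks)
    if ratio >= max_fold or ratio <= 1.0 / max_fold:
        return False, "depth_fold_%.2f" % ratio
    return True, "PASS"


# ---------------------------------------------------------------------------
# Cluster annotation and the end-to-end caller
# ---------------------------------------------------------------------------

def _oriented_payload(sig: InsertionSignal, strand: str, tsd: Optional[str]) -> str:
    """Insertion sequence in element-forward orientation, TSD removed."""
    seq = sig.ins_seq
    if tsd and seq.startswith(tsd[0]) and len(seq) > len(tsd):
        # TSD is prefix-anchored for left-aligned signals, suffix for right
        if seq[: len(tsd)] == tsd:
            seq = seq[len(tsd) :]
        elif seq[-len(tsd) :] == tsd:
            seq = seq[: -len(tsd)]
    return seq if strand == "+" else revcomp(seq)


def annotate_cluster(
    cluster: CallCluster,
    consensus_lib: Sequence[SequenceRecord],
    features: Sequence[RepeatFeature] = (),
    params: CallerParams = CallerParams(),
) -> MEICallRecord:
    """Attach subfamily, strand, hallmarks, and status to one cluster."""
    members = sorted(cluster.signals, key=lambda s: len(s.ins_seq), reverse=True)
    votes: dict[str, int] = {}
    rep_assign = None
    for s in members[:5]:
        fam, sub, strand, inv = assign_subfamily(s.ins_seq, consensus_lib, params.subfamily_min_score)
        votes[sub] = votes.get(sub, 0) + 1
        if rep_assign is None:
            rep_assign = (fam, sub, strand, inv)
    subfamily = max(votes, key=lambda k: (votes[k], k != "unknown"))
    fam, _, strand, inverted5 = rep_assign if rep_assign else ("unknown", "unknown", "+", False)
    if subfamily != rep_assign[1]:
        fam = family_of(subfamily)

    # hallmarks: TSD from the first signal that shows one, poly(A) and
    # transduction from the best (longest) insertion sequence
    tsd = None
    for s in members[:8]:
        cand = detect_tsd(s.ins_seq, s.flank5, s.flank3, params.min_tsd, params.max_tsd, params.tsd_max_mismatch)
        if cand and (tsd is None or len(cand) > len(tsd)):
            tsd = cand  # longest candidate: clips missing the junction can
            # only produce short coincidental words
    rep = members[0]
    payload = _oriented_payload(rep, strand, tsd)
    # poly(A) may live in a different member than the longest one (a clip
    # entering from the 5' side never reaches the tract): take the max
    polya = 0
    for s in members[:8]:
        p = _oriented_payload(s, strand, tsd)
        polya = max(
            polya, detect_polya(p, "+", params.polya_min_len, params.polya_purity, params.polya_window)
        )
    en = 0
    if rep.flank5 and rep.flank3 and len(rep.flank5) >= 4 and len(rep.flank3) >= 2:
        en = detect_en_motif(rep.flank5[-4:] + rep.flank3[:2])
    transduction = None
    core = payload[: len(payload) - polya] if polya else payload
    if core and subfamily != "unknown":
        cons = next((c for c in consensus_lib if c.id == subfamily), None)
        if cons is not None and len(core) >= params.transduction_min_len:
            probe = core[-600:]  # transductions longer than ~570 bp are capped
            _, _, _, _, q_end = best_local(probe, cons.seq)
            tail = probe[q_end:]
            if len(tail) >= params.transduction_min_len:
                transduction = tail

    status = "non_reference"
    for f in features:
        if (
            f.ref_name == cluster.ref_name
            and f.subfamily == subfamily
            and f.start - params.cluster_window <= cluster.position <= f.end + params.cluster_window
        ):
            status = "reference"
            break

    length = int(statistics.median(len(s.ins_seq) for s in cluster.signals))
    call = MEICallRecord(
        ref_name=cluster.ref_name,
        position=cluster.position,
        subfamily=subfamily,
        strand=strand,
        length=length,
        support=cluster.support,
        hallmarks=Hallmarks(
            tsd=tsd,
            polya_len=polya,
            en_site_score=en,
            transduction_seq=transduction,
            inverted5=inverted5,
        ),
        status=status,
    )
    cluster.call = call
    return call


def call_nonreference(
    reads: Sequence[QualityRead],
    alns: Sequence[AlignmentRecord],
    features: Sequence[RepeatFeature],
    consensus_lib: Sequence[SequenceRecord],
    genome: Optional[SequenceRecord] = None,
    params: CallerParams = CallerParams(),
) -> list[MEICallRecord]:
    """End-to-end non-reference MEI calling on one run.

    Quality filter, MAPQ filter, pre-masking, signal extraction,
    clustering, hallmark annotation, genotyping, optional depth filter;
    calls landing inside an annotated element of the same subfamily are
    flagged ``status=reference`` instead of non-reference.
    """
    kept, _ = filter_reads(reads, params.min_q)
    seqs = {r.id: r.seq for r in kept}
    primary: dict[str, AlignmentRecord] = {}
    for a in alns:
        if a.read_id in seqs and a.mapq >= params.min_mapq and a.read_id not in primary:
            primary[a.read_id] = a

    mei_families = {"L1", "Alu", "SVA"}
    signals: list[InsertionSignal] = []
    for a in primary.values():
        masked = project_annotation_to_read(a, features, mei_families)
        signals.extend(extract_insertion_signals(a, seqs[a.read_id], masked, genome, params))

    clusters = cluster_supporting_reads(signals, params.cluster_window, params.min_support)
    coverage = None
    if params.depth_filter and genome is not None:
        coverage = [0] * len(genome.seq)
        for a in primary.values():
            for i in range(a.ref_start, min(a.ref_end, len(coverage))):
                coverage[i] += 1

    calls: list[MEICallRecord] = []
    for cl in clusters:
        call = annotate_cluster(cl, consensus_lib, features, params)
        member_ids = {s.read_id for s in cl.signals}
        covering: set[str] = set()
        empty = False
        m = params.span_margin
        for a in primary.values():
            if a.ref_name == cl.ref_name and a.ref_start + m <= cl.position <= a.ref_end - m:
                covering.add(a.read_id)
                if a.read_id not in member_ids:
                    empty = True
        # clip-supported members touch the locus without spanning it; they
        # still sample a haplotype, so they join the denominator
        span = len(covering | member_ids)
        call.hallmarks.empty_site_ok = empty
        call.genotype = genotype_call(
            cl.support, span, params.hom_threshold, params.het_threshold
        )
        cl.span_reads_total = span
        if coverage is not None:
            ok, reason = apply_depth_filter(cl.position, coverage, params.depth_bin, params.depth_max_fold)
            call.filter = "PASS" if ok else reason
        calls.append(call)
    calls.sort(key=lambda c: (c.ref_name, c.position))
    return calls
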