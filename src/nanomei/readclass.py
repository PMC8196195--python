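"""Read QC, MEI end-scan, repeat pre-masking, and on/close/off-target calls.

The front end of the enrichment analysis: reads passing the quality filter
are scanned for mobile-element signal in their terminal bins, annotated
reference repeats are projected through the alignment onto read
coordinates (pre-masking), and every read is placed in exactly one
category — on-target (reference or non-reference), close-target,
off-target, or discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import scan_aligner
from .seqio import (
    AlignmentRecord,
    QualityRead,
    RepeatFeature,
    SequenceRecord,
    family_of,
    revcomp,
)

__all__ = [
    "MEISignal",
    "ReadClassification",
    "MaskedRead",
    "TargetRateTable",
    "filter_reads",
    "scan_read_for_mei",
    "project_annotation_to_read",
    "classify_read",
    "tally_target_rates",
]

CATEGORIES = (
    "on_target_reference",
    "on_target_nonreference",
    "close_target",
    "off_target",
    "discarded_mapq",
    "discarded_quality",
)

DEFAULT_SCAN_THRESHOLD = 60.0  # local score over a 100 bp bin (~30 matched bases)
MIN_MAPQ = 10
MIN_ON_TARGET_OVERLAP = 100  # bp of read/element overlap counting as on-target


@dataclass
class MEISignal:
    family: str
    subfamily_best: str
    location: str  # end3 | end5 | both | middle | none
    score: float
    read_intervals: tuple[tuple[int, int], ...] = ()

    @classmethod
    def none(cls) -> "MEISignal":
        return cls("", "", "none", 0.0, ())


@dataclass
class ReadClassification:
    read_id: str
    category: str
    basis: str = ""


@dataclass
class MaskedRead:
    read_id: str
    read_len: int
    masked_intervals: tuple[tuple[int, int], ...]

    @property
    def unmasked_intervals(self) -> tuple[tuple[int, int], ...]:
        out = []
        prev = 0
        for a, b in self.masked_intervals:
            if a > prev:
                out.append((prev, a))
            prev = b
        if prev < self.read_len:
            out.append((prev, self.read_len))
        return tuple(out)

    def masked_fraction(self, a: int, b: int) -> float:
        if b <= a:
            return 0.0
        cov = sum(max(0, min(b, y) - max(a, x)) for x, y in self.masked_intervals)
        return cov / (b - a)


def filter_reads(reads: Sequence[QualityRead], min_q: float = 7.0) -> tuple[list[QualityRead], list[QualityRead]]:
    """Partition reads by mean Q-score; kept iff strictly above ``min_q``."""
    kept, dropped = [], []
    for r in reads:
        (kept if r.mean_q > min_q else dropped).append(r)
    return kept, dropped


def scan_read_for_mei(
    read: QualityRead | SequenceRecord,
    consensus_lib: Sequence[SequenceRecord],
    bin_bp: int = 100,
    threshold: float = DEFAULT_SCAN_THRESHOLD,
    interior: bool = False,
) -> MEISignal:
    """Scan terminal bins (and optionally interior windows) for MEI signal.

    Each bin is locally aligned against every consensus (both strands);
    a terminal bin scoring at or above the threshold marks end5/end3
    signal, interior-only hits mark ``middle``.
    """
    if not consensus_lib:
        raise ValueError("empty consensus library")
    seq = read.seq
    aligner = scan_aligner()

    def bin_hit(s: str) -> tuple[float, str]:
        best, name = 0.0, ""
        for cons in consensus_lib:
            for t in (cons.seq, revcomp(cons.seq)):
                score = float(aligner.score(t, s))
                if score > best:
                    best, name = score, cons.id
        return best, name

    if len(seq) <= 2 * bin_bp:
        score, name = bin_hit(seq)
        if score >= threshold:
            return MEISignal(family_of(name), name, "both", score, ((0, len(seq)),))
        return MEISignal.none()

    s5, n5 = bin_hit(seq[:bin_bp])
    s3, n3 = bin_hit(seq[-bin_bp:])
    hit5, hit3 = s5 >= threshold, s3 >= threshold
    if hit5 and hit3:
        name = n5 if s5 >= s3 else n3
        return MEISignal(family_of(name), name, "both", max(s5, s3), ((0, bin_bp), (len(seq) - bin_bp, len(seq))))
    if hit5:
        return MEISignal(family_of(n5), n5, "end5", s5, ((0, bin_bp),))
    if hit3:
        return MEISignal(family_of(n3), n3, "end3", s3, ((len(seq) - bin_bp, len(seq)),))
    if interior:
        best, name, where = 0.0, "", (0, 0)
        for start in range(bin_bp, len(seq) - 2 * bin_bp + 1, bin_bp):
            sc, nm = bin_hit(seq[start : start + bin_bp])
            if sc > best:
                best, name, where = sc, nm, (start, start + bin_bp)
        if best >= threshold:
            return MEISignal(family_of(name), name, "middle", best, (where,))
    return MEISignal.none()


def project_annotation_to_read(
    aln: AlignmentRecord, features: Sequence[RepeatFeature], families: Optional[set[str]] = None
) -> MaskedRead:
    """Map annotated repeat intervals through the CIGAR onto read coordinates.

    Deletions collapse; insertions inside a feature stay unmasked.  Read
    coordinates are reported on the original read (strand-resolved).
    """
    feats = [
        f
        for f in features
        if f.ref_name == aln.ref_name
        and f.start < aln.ref_end
        and f.end > aln.ref_start
        and (families is None or f.family in families)
    ]
    intervals: list[tuple[int, int]] = []
    for f in feats:
        qpos, rpos = 0, aln.ref_start
        for op, n in aln.cigar:
            if op in "M=X":
                lo = max(rpos, f.start)
                hi = min(rpos + n, f.end)
                if lo < hi:
                    # one interval per aligned block: insertions between
                    # blocks (even inside the feature) stay unmasked
                    intervals.append((qpos + (lo - rpos), qpos + (hi - rpos)))
                qpos += n
                rpos += n
            elif op in "ISH":
                qpos += n
            elif op in "DN":
                rpos += n
    intervals.sort()
    merged: list[tuple[int, int]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    if aln.strand == "-":
        n = aln.read_len
        merged = sorted((n - b, n - a) for a, b in merged)
    return MaskedRead(aln.read_id, aln.read_len, tuple(merged))


#: close-target subfamily prefixes per experiment family; everything else in
#: the same repeat family is off-target (SVA defines no off when signal).
def _target_sets(experiment_subfamily: str) -> tuple[str, set[str] | None]:
    fam = family_of(experiment_subfamily)
    if fam not in ("L1", "Alu", "SVA"):
        raise ValueError(f"unknown experiment family for {experiment_subfamily!r}")
    return fam, None


def _element_role(subfamily: str, experiment_subfamily: str) -> str:
    """target / close / off / other for a reference element identity."""
    fam = family_of(experiment_subfamily)
    efam = family_of(subfamily)
    if subfamily == experiment_subfamily:
        return "target"
    if fam == "L1":
        if subfamily in ("L1Ta", "L1PreTa", "L1HS"):
            return "target"
        if subfamily.startswith("L1PA"):
            return "close"
        return "off" if efam == "L1" else "other"
    if fam == "Alu":
        if subfamily.startswith("AluY"):
            return "close"
        return "off" if efam == "Alu" else "other"
    # SVA experiments: other SVAs are close; off is never assigned on signal
    if efam == "SVA":
        return "close"
    return "other"


def classify_read(
    read: QualityRead | str,
    aln: Optional[AlignmentRecord],
    signal: Optional[MEISignal],
    masked: Optional[MaskedRead],
    palmer_hit: bool,
    experiment_subfamily: str,
    features: Sequence[RepeatFeature] = (),
    min_mapq: int = MIN_MAPQ,
    min_overlap: int = MIN_ON_TARGET_OVERLAP,
) -> ReadClassification:
    """One category per read, in order of precedence:

    1. unaligned or MAPQ below threshold -> discarded_mapq;
    2. a pre-masking (PALMER) insertion hit -> on_target_nonreference;
    3. alignment into a reference element of the target subfamily ->
       on_target_reference;
    4. family rules for related reference elements (L1PA close / other L1
       off for L1Hs runs; other AluY close / other Alu off; other SVA
       close, never off while an SVA signal is present);
    5. otherwise off_target.
    """
    read_id = read if isinstance(read, str) else read.id
    _target_sets(experiment_subfamily)  # validates the family
    if aln is None or aln.mapq < min_mapq:
        return ReadClassification(read_id, "discarded_mapq", "unaligned or MAPQ < %d" % min_mapq)
    if palmer_hit:
        return ReadClassification(read_id, "on_target_nonreference", "pre-masking insertion signal")

    overlaps: dict[str, int] = {}
    for f in features:
        if f.ref_name != aln.ref_name:
            continue
        ov = min(aln.ref_end, f.end) - max(aln.ref_start, f.start)
        if ov >= min_overlap:
            role = _element_role(f.subfamily, experiment_subfamily)
            overlaps[role] = max(overlaps.get(role, 0), ov)
    if "target" in overlaps:
        return ReadClassification(read_id, "on_target_reference", "maps into reference target element")
    if "close" in overlaps:
        return ReadClassification(read_id, "close_target", "maps into related reference subfamily")
    has_signal = signal is not None and signal.location != "none"
    if "off" in overlaps:
        if family_of(experiment_subfamily) == "SVA" and has_signal:
            return ReadClassification(read_id, "close_target", "SVA signal; off-target undefined")
        return ReadClassification(read_id, "off_target", "maps into unrelated reference repeat")
    if has_signal and family_of(experiment_subfamily) == "SVA" and signal.family == "SVA":
        return ReadClassification(read_id, "close_target", "SVA signal; off-target undefined")
    return ReadClassification(read_id, "off_target", "no target overlap" + ("" if has_signal else "; no MEI signal"))


@dataclass
class TargetRateTable:
    run: str
    subfamily: str
    n_reads: int                      # non-discarded reads
    counts: dict[str, int]
    fractions: dict[str, float]
    read_len_by_location: dict[str, float] = field(default_factory=dict)

    @property
    def on_target_rate(self) -> float:
        return self.fractions["on_target_reference"] + self.fractions["on_target_nonreference"]

    def row(self) -> dict:
        return {
            "run": self.run,
            "subfamily": self.subfamily,
            "n_reads": self.n_reads,
            "on_ref_pct": 100 * self.fractions["on_target_reference"],
            "on_nonref_pct": 100 * self.fractions["on_target_nonreference"],
            "close_pct": 100 * self.fractions["close_target"],
            "off_pct": 100 * self.fractions["off_target"],
        }


def tally_target_rates(
    classifications: Sequence[ReadClassification],
    signals: Optional[dict[str, MEISignal]] = None,
    reads: Optional[dict[str, int]] = None,
    run: str = "run",
    subfamily: str = "",
) -> TargetRateTable:
    """Category counts and fractions over non-discarded reads; mean read
    length by signal location when signals and read lengths are supplied."""
    if not classifications:
        raise ValueError("no classifications to tally")
    counts = {c: 0 for c in CATEGORIES}
    for c in classifications:
        counts[c.category] += 1
    n = sum(counts[c] for c in CATEGORIES[:4])
    if n == 0:
        raise ValueError("all reads were discarded")
    fractions = {c: counts[c] / n for c in CATEGORIES[:4]}
    by_loc: dict[str, float] = {}
    if signals is not None and reads is not None:
        groups: dict[str, list[int]] = {}
        for rid, sig in signals.items():
            if rid in reads:
                loc = "end" if sig.location in ("end5", "end3") else sig.location
                groups.setdefault(loc, []).append(reads[rid])
        by_loc = {loc: float(np.mean(v)) for loc, v in groups.items() if v}
    return TargetRateTable(run, subfamily, n, counts, fractions, by_loc)
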