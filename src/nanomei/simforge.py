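"""Synthetic-data generator for the whole pipeline.

Everything the pipeline consumes — reference genome with annotated repeat
copies, a diploid donor carrying TPRT-hallmarked non-reference insertions,
Cas9-cut nanopore-like reads with truth alignments — is produced here from
a single integer seed, so every module is testable without downloads.

The packaged toy consensus set mimics the active human retrotransposon
subfamilies: a ~6 kb L1Hs-like element (with an older, diverged L1PA2-like
outgroup), ~300 bp AluYb8/AluYa5-like elements (AluYb8 carrying the 7 bp
CAGTCCG diagnostic insertion) with an AluY outgroup, and ~1.4 kb
SVA_F/SVA_E-like elements with an SVA_D outgroup.  Each target consensus
carries an engineered guide site near (but not at) its 3' end: a 20 bp
protospacer + NGG PAM whose window contains subfamily-diagnostic bases,
one of them on a PAM G so a Tier0 guide exists.  Real Repbase consensus
files are drop-in replacements.

Truth-unambiguity conventions (documented in docs/methods.md): implant
sites are chosen so the two reference bases following the duplicated
target word differ from the first two payload bases, and toy consensus
sequences end in five non-A bases — this makes the implanted TSD and
poly(A) strings the unique maximal hallmark words, so error-free recovery
can be checked by string equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np

import edlib

from .seqio import (
    AlignmentRecord,
    QualityRead,
    RepeatFeature,
    SequenceRecord,
    family_of,
    revcomp,
    write_fasta,
    write_fastq,
    write_paf,
    write_repeat_annotation,
)

__all__ = [
    "SimConfig",
    "FamilyConfig",
    "NonRefConfig",
    "ReadConfig",
    "TruthLocus",
    "TruthSet",
    "SimRun",
    "toy_consensus_library",
    "toy_guide",
    "TOY_GUIDE_SITES",
    "build_reference",
    "implant_nonreference",
    "simulate_cas9_run",
    "simulate_wgs_run",
    "write_run",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
EN_MOTIF = "TTTTAA"  # L1 endonuclease consensus 5'-TTTT/AA


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate_subs(seq: str, rng: np.random.Generator, rate: float, protect: tuple[tuple[int, int], ...] = ()) -> str:
    """Substitute bases at ``rate``, never inside protected windows."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for a, b in protect:
        hit[a:b] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Toy consensus library
# ---------------------------------------------------------------------------

_TOY_SEED = 1463  # fixed forever: the library is part of the package contract

#: 0-based start of the engineered 23-mer guide site on each target consensus.
TOY_GUIDE_SITES: dict[str, int] = {
    "L1Hs": 5717,
    "AluYb8": 60,
    "AluYa5": 110,
    "SVA_F": 1120,
    "SVA_E": 1060,
}

# per-site diagnostic layout: offsets within the 23-mer window and the
# (target, outgroup) base at each; offset 21 sits on the first PAM G.
_DIAG = ((6, "C", "T"), (13, "A", "G"), (21, "G", "A"))


def _engineer_site(seqs: dict[str, list[str]], target: str, outgroups: tuple[str, ...], gpos: int) -> None:
    for name in (target, *outgroups):
        seqs[name][gpos + 22] = "G"  # shared second PAM G
    for off, tbase, obase in _DIAG:
        seqs[target][gpos + off] = tbase
        for out in outgroups:
            seqs[out][gpos + off] = obase


@lru_cache(maxsize=1)
def toy_consensus_library() -> dict[str, SequenceRecord]:
    """Deterministic synthetic consensus set (synthetic stand-ins, not Repbase)."""
    rng = np.random.default_rng(_TOY_SEED)
    tail = "GTCGC"  # non-A 3' terminus for unambiguous poly(A) truth

    l1 = list(_rand_seq(rng, 6000))
    l1[-5:] = tail
    alu = list(_rand_seq(rng, 300))
    alu[-5:] = tail
    sva = list(_rand_seq(rng, 1400))
    sva[-5:] = tail

    seqs = {
        "L1Hs": l1[:],
        "L1PA2": l1[:],
        "AluY": alu[:],
        "AluYa5": alu[:],
        "AluYb8": alu[:],
        "SVA_D": sva[:],
        "SVA_E": sva[:],
        "SVA_F": sva[:],
    }
    _engineer_site(seqs, "L1Hs", ("L1PA2",), TOY_GUIDE_SITES["L1Hs"])
    _engineer_site(seqs, "AluYb8", ("AluY", "AluYa5"), TOY_GUIDE_SITES["AluYb8"])
    _engineer_site(seqs, "AluYa5", ("AluY", "AluYb8"), TOY_GUIDE_SITES["AluYa5"])
    _engineer_site(seqs, "SVA_F", ("SVA_D", "SVA_E"), TOY_GUIDE_SITES["SVA_F"])
    _engineer_site(seqs, "SVA_E", ("SVA_D", "SVA_F"), TOY_GUIDE_SITES["SVA_E"])

    # background divergence of the outgroups, clear of every engineered site
    protected = tuple((g, g + 23) for g in TOY_GUIDE_SITES.values())
    for out, rate in (("L1PA2", 0.03), ("AluY", 0.04), ("AluYa5", 0.0), ("SVA_D", 0.03)):
        seqs[out] = list(_mutate_subs("".join(seqs[out]), rng, rate, protected))
    # AluYb8 diagnostic 7 bp insertion unique to the youngest Alu lineage
    yb = seqs["AluYb8"]
    seqs["AluYb8"] = yb[:230] + list("CAGTCCG") + yb[230:]

    out: dict[str, SequenceRecord] = {}
    for name, chars in seqs.items():
        role = "target_consensus" if name in TOY_GUIDE_SITES else "outgroup_consensus"
        out[name] = SequenceRecord(name, "".join(chars), role)
    return out


def toy_guide(subfamily: str) -> str:
    """The engineered 23-mer (20 bp guide + NGG PAM) for a toy subfamily."""
    lib = toy_consensus_library()
    g = TOY_GUIDE_SITES[subfamily]
    return lib[subfamily].seq[g : g + 23]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilyConfig:
    subfamily: str
    copies: int
    divergence: float = 0.02
    min_len: int = 400
    max_len: int = 0  # 0 -> full consensus length
    random_strand: bool = True


@dataclass
class NonRefConfig:
    count: int = 10
    subfamily: str = "L1Hs"
    het_fraction: float = 0.5
    full_length_prob: float = 0.25
    min_len: int = 400
    max_len: int = 1500
    tsd_range: tuple[int, int] = (5, 20)
    polya_range: tuple[int, int] = (10, 40)
    inversion_prob: float = 0.0
    random_strand: bool = True
    en_candidates: int = 40  # implant sites drawn per locus; best EN match wins


@dataclass
class ReadConfig:
    reads_per_cut: float = 10.0
    poisson: bool = True
    cut_offsets_fwd: dict[int, float] = field(default_factory=lambda: {3: 0.5, 4: 0.5})
    cut_offsets_rev: dict[int, float] = field(default_factory=lambda: {7: 1.0})
    strand_bias: float = 4.6
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    n50: int = 5000
    sigma: float = 0.6
    min_len: int = 300
    background_fraction: float = 0.2
    mean_q: float = 12.0
    low_q_fraction: float = 0.0  # reads emitted below the Q filter, for QC tests


@dataclass
class SimConfig:
    seed: int
    genome_len: int = 200_000
    families: tuple[FamilyConfig, ...] = (
        FamilyConfig("L1Hs", 10),
        FamilyConfig("L1PA2", 6, divergence=0.03),
        FamilyConfig("AluYb8", 8, min_len=250),
        FamilyConfig("AluYa5", 6, min_len=250),
        FamilyConfig("AluY", 6, divergence=0.04, min_len=250),
        FamilyConfig("SVA_F", 3, min_len=600),
        FamilyConfig("SVA_E", 3, min_len=600),
    )
    nonref: NonRefConfig = field(default_factory=NonRefConfig)
    reads: ReadConfig = field(default_factory=ReadConfig)
    chrom: str = "chr1"


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthLocus:
    locus_id: str
    position: int          # reference breakpoint (0-based); TSD word starts here
    subfamily: str
    strand: str
    element_len: int
    polya_len: int
    tsd: str
    zygosity: str          # het | hom
    haplotypes: tuple[int, ...]
    inverted5: bool
    payload: str           # oriented element+poly(A), as inserted

    @property
    def ins_len(self) -> int:
        return len(self.tsd) + len(self.payload)


@dataclass
class TruthSet:
    config: SimConfig
    genome: SequenceRecord
    features: list[RepeatFeature]
    consensus: dict[str, SequenceRecord]
    haplotypes: tuple[str, str] = ("", "")
    loci: list[TruthLocus] = field(default_factory=list)

    def hap_insertions(self, hap: int) -> list[tuple[int, int, str]]:
        """(ref_pos, ins_len, ins_seq) for one haplotype, sorted by position."""
        out = []
        for loc in self.loci:
            if hap in loc.haplotypes:
                out.append((loc.position, loc.ins_len, loc.tsd + loc.payload))
        return sorted(out)


@dataclass
class ReadProvenance:
    read_id: str
    hap: int
    locus_id: Optional[str]   # None for background reads
    frame: str                # fwd | rev | bg
    cut_offset: int           # -1 for background
    mapped: bool


@dataclass
class SimRun:
    reads: list[QualityRead]
    alignments: list[AlignmentRecord]
    provenance: list[ReadProvenance]
    manifest: dict


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _place_intervals(
    rng: np.random.Generator, genome_len: int, lengths: list[int], taken: list[tuple[int, int]], margin: int = 500
) -> list[int]:
    starts = []
    for ln in lengths:
        for _ in range(200):
            s = int(rng.integers(margin, genome_len - ln - margin))
            if all(s + ln + margin <= a or s >= b + margin for a, b in taken):
                taken.append((s, s + ln))
                starts.append(s)
                break
        else:
            raise ValueError("overcrowded simulation config: could not place all elements")
    return starts


def build_reference(config: SimConfig) -> TruthSet:
    """Random background genome with implanted, per-copy-diverged repeat copies."""
    rng = np.random.default_rng([config.seed, 0])
    genome = list(_rand_seq(rng, config.genome_len))
    lib = toy_consensus_library()
    taken: list[tuple[int, int]] = []
    features: list[RepeatFeature] = []

    for fam in config.families:
        cons = lib[fam.subfamily].seq
        max_len = fam.max_len or len(cons)
        lengths = [int(rng.integers(fam.min_len, max_len + 1)) for _ in range(fam.copies)]
        starts = _place_intervals(rng, config.genome_len, lengths, taken)
        for s, ln in zip(starts, lengths):
            copy = cons[len(cons) - ln :]  # 5'-truncated copy keeps the 3' end
            copy = _mutate_subs(copy, rng, fam.divergence)
            strand = "+"
            if fam.random_strand and rng.random() < 0.5:
                strand = "-"
                copy = revcomp(copy)
            genome[s : s + ln] = copy
            features.append(
                RepeatFeature(config.chrom, s, s + ln, strand, family_of(fam.subfamily), fam.subfamily)
            )
    features.sort(key=lambda f: f.start)
    return TruthSet(
        config=config,
        genome=SequenceRecord(config.chrom, "".join(genome), "genome"),
        features=features,
        consensus=lib,
    )


# ---------------------------------------------------------------------------
# Non-reference implants (diploid donor)
# ---------------------------------------------------------------------------

def _en_score(window: str) -> int:
    return sum(a == b for a, b in zip(window, EN_MOTIF))


def implant_nonreference(truth: TruthSet) -> TruthSet:
    """Insert TPRT cassettes [TSD][element|poly(A)][TSD] into a diploid donor.

    Sites are biased toward the L1 endonuclease motif (the best of
    ``en_candidates`` random positions by TTTT/AA match count wins) and are
    constrained so the implanted TSD and poly(A) are unambiguous truth.
    """
    config = truth.config
    nr = config.nonref
    rng = np.random.default_rng([config.seed, 1])
    ref = truth.genome.seq
    lib = truth.consensus
    cons = lib[nr.subfamily].seq
    forbidden = [(f.start - 500, f.end + 500) for f in truth.features]
    loci: list[TruthLocus] = []

    for i in range(nr.count):
        # element, possibly 5'-truncated, possibly 5'-inverted (twin priming)
        if rng.random() < nr.full_length_prob:
            el = cons
        else:
            ln = int(rng.integers(nr.min_len, min(nr.max_len, len(cons)) + 1))
            el = cons[len(cons) - ln :]
        inverted5 = False
        if family_of(nr.subfamily) == "L1" and rng.random() < nr.inversion_prob:
            split = int(rng.integers(100, len(el) - 300))
            el = revcomp(el[:split]) + el[split:]
            inverted5 = True
        polya_len = int(rng.integers(nr.polya_range[0], nr.polya_range[1] + 1))
        strand = "-" if (nr.random_strand and rng.random() < 0.5) else "+"
        cassette = el + "A" * polya_len
        payload = cassette if strand == "+" else revcomp(cassette)
        tsd_len = int(rng.integers(nr.tsd_range[0], nr.tsd_range[1] + 1))

        placed = False
        for _ in range(60):
            cands = rng.integers(2000, len(ref) - 2000, nr.en_candidates)
            scores = [_en_score(ref[p - 4 : p + 2]) for p in cands]
            order = np.argsort(scores)[::-1]
            for j in order:
                p = int(cands[j])
                if not all(p < a or p > b for a, b in forbidden):
                    continue
                tsd = ref[p : p + tsd_len]
                # truth-unambiguity: junction bases must break the TSD word
                if ref[p + tsd_len] == payload[0] or ref[p + tsd_len + 1] == payload[1]:
                    continue
                if "N" in tsd:
                    continue
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ValueError("could not place non-reference implant (overcrowded config)")
        forbidden.append((p - 3000, p + 3000))

        if rng.random() < (1 - nr.het_fraction):
            haps: tuple[int, ...] = (0, 1)
            zyg = "hom"
        else:
            haps = (int(rng.integers(0, 2)),)
            zyg = "het"
        loci.append(
            TruthLocus(
                locus_id=f"nr{i:03d}",
                position=p,
                subfamily=nr.subfamily,
                strand=strand,
                element_len=len(el),
                polya_len=polya_len,
                tsd=tsd,
                zygosity=zyg,
                haplotypes=haps,
                inverted5=inverted5,
                payload=payload,
            )
        )

    loci.sort(key=lambda l: l.position)
    haplotypes = []
    for hap in (0, 1):
        parts, prev = [], 0
        for loc in loci:
            if hap not in loc.haplotypes:
                continue
            parts.append(ref[prev : loc.position])
            parts.append(loc.tsd + loc.payload)
            prev = loc.position
        parts.append(ref[prev:])
        haplotypes.append("".join(parts))
    truth.haplotypes = (haplotypes[0], haplotypes[1])
    truth.loci = loci
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _hap_segments(truth: TruthSet, hap: int) -> list[tuple[int, int, str, int]]:
    """Alternating (hap_start, hap_end, kind, ref_start) segments; kind M or I."""
    segs = []
    hap_pos = 0
    ref_pos = 0
    for p, ln, _seq in truth.hap_insertions(hap):
        if p > ref_pos:
            segs.append((hap_pos, hap_pos + (p - ref_pos), "M", ref_pos))
            hap_pos += p - ref_pos
            ref_pos = p
        segs.append((hap_pos, hap_pos + ln, "I", ref_pos))
        hap_pos += ln
    ref_len = len(truth.genome.seq)
    if ref_pos < ref_len:
        segs.append((hap_pos, hap_pos + (ref_len - ref_pos), "M", ref_pos))
    return segs


def _structural_cigar(segs, a: int, b: int) -> tuple[list[tuple[str, int]], Optional[int]]:
    """CIGAR of hap interval [a, b) against the reference, before errors."""
    ops: list[tuple[str, int]] = []
    ref_start = None
    for hs, he, kind, rs in segs:
        if he <= a or hs >= b:
            continue
        lo, hi = max(hs, a), min(he, b)
        if kind == "M" and ref_start is None:
            ref_start = rs + (lo - hs)
        ops.append((kind, hi - lo))
    return ops, ref_start


def _apply_errors(
    seq: str, ops: list[tuple[str, int]], rng: np.random.Generator, rc: ReadConfig
) -> tuple[str, list[tuple[str, int]]]:
    """Per-base independent sub/ins/del errors, rewriting seq and CIGAR."""
    if rc.sub_rate == rc.ins_rate == rc.del_rate == 0:
        return seq, ops
    out_ops: list[tuple[str, int]] = []
    out_seq: list[str] = []
    pos = 0

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if out_ops and out_ops[-1][0] == op:
            out_ops[-1] = (op, out_ops[-1][1] + n)
        else:
            out_ops.append((op, n))

    for op, n in ops:
        if op == "D":
            push("D", n)
            continue
        chunk = np.frombuffer(seq[pos : pos + n].encode(), dtype=np.uint8).copy()
        pos += n
        u = rng.random(n)
        dels = u < rc.del_rate
        inss = (~dels) & (u < rc.del_rate + rc.ins_rate)
        subs = (~dels) & (~inss) & (u < rc.del_rate + rc.ins_rate + rc.sub_rate)
        for i in np.nonzero(subs)[0]:
            choices = _BASES[_BASES != chunk[i]]
            chunk[i] = choices[rng.integers(0, len(choices))]
        if op in "IS":  # read-only ops: length just changes
            kept = chunk[~dels].tobytes().decode()
            extra_at = np.nonzero(inss)[0]
            pieces, prev = [], 0
            arr = chunk[~dels]
            # map insertion positions onto the kept array
            keep_index = np.cumsum(~dels) - 1
            marks = sorted(set(int(keep_index[i]) for i in extra_at if not dels[i]))
            s = arr.tobytes().decode()
            for m in marks:
                pieces.append(s[prev : m + 1])
                pieces.append(_BASES[rng.integers(0, 4)].tobytes().decode())
                prev = m + 1
            pieces.append(s[prev:])
            new = "".join(pieces) if marks else kept
            out_seq.append(new)
            push(op, len(new))
            continue
        # M segment: emit M/I/D runs
        cursor = 0
        events = sorted(np.nonzero(dels | inss)[0])
        s = chunk.tobytes().decode()
        for i in events:
            if dels[i]:
                push("M", i - cursor)
                out_seq.append(s[cursor:i])
                push("D", 1)
                cursor = i + 1
            else:  # insertion after base i
                push("M", i + 1 - cursor)
                out_seq.append(s[cursor : i + 1])
                push("I", 1)
                out_seq.append(_BASES[rng.integers(0, 4)].tobytes().decode())
                cursor = i + 1
        push("M", n - cursor)
        out_seq.append(s[cursor:])
    return "".join(out_seq), out_ops


def _finish_ops(ops: list[tuple[str, int]]) -> Optional[list[tuple[str, int]]]:
    """Turn terminal I into S, drop terminal D; None if nothing aligns."""
    ops = [op for op in ops if op[1] > 0]
    while ops and ops[0][0] in "ID":
        op, n = ops.pop(0)
        if op == "I":
            ops.insert(0, ("S", n))
            break
    while ops and ops[-1][0] in "ID":
        op, n = ops.pop()
        if op == "I":
            ops.append(("S", n))
            break
    # merge soft clips created next to existing ones
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if not any(op in "M=X" for op, _ in merged):
        return None
    return merged


def _read_length(rng: np.random.Generator, rc: ReadConfig) -> int:
    mu = np.log(rc.n50) - rc.sigma**2
    ln = int(np.exp(rng.normal(mu, rc.sigma)))
    return max(rc.min_len, ln)


def _sample_offset(rng: np.random.Generator, dist: dict[int, float]) -> int:
    ks = sorted(dist)
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return int(rng.choice(ks, p=ps))


def _make_read(
    truth: TruthSet,
    segs,
    hap: int,
    a: int,
    b: int,
    orient: str,
    name: str,
    rng: np.random.Generator,
    rc: ReadConfig,
    qual: int,
) -> tuple[QualityRead, Optional[AlignmentRecord]]:
    """One read over hap interval [a, b); orient '-' stores the revcomp."""
    hap_seq = truth.haplotypes[hap]
    a, b = max(0, a), min(len(hap_seq), b)
    base_seq = hap_seq[a:b]
    ops, ref_start = _structural_cigar(segs, a, b)
    seq, ops = _apply_errors(base_seq, ops, rng, rc)
    stored = seq if orient == "+" else revcomp(seq)
    read = QualityRead(name, stored, (qual,) * len(stored))
    fin = _finish_ops(ops)
    if fin is None or ref_start is None:
        return read, None
    lead = fin[0][1] if fin[0][0] == "S" else 0
    tail = fin[-1][1] if fin[-1][0] == "S" else 0
    n = len(stored)
    if orient == "+":
        read_start, read_end = lead, n - tail
    else:
        read_start, read_end = tail, n - lead
    # clips in the structural CIGAR consumed reference-matched hap bases? no:
    # leading S always came from I segments, so ref_start is the first M base.
    skipped_m = 0
    aln = AlignmentRecord(
        read_id=name,
        read_len=n,
        read_start=read_start,
        read_end=read_end,
        strand=orient,
        ref_name=truth.genome.id,
        ref_start=ref_start + skipped_m,
        ref_end=ref_start + sum(x for o, x in fin if o in "MD=X"),
        mapq=60,
        cigar=tuple(fin),
    )
    aln.validate()
    return read, aln


def find_guide_sites(guide: str, seq: str, max_dist: int = 3) -> list[tuple[int, int]]:
    """(pam_n_position, direction) of guide matches on both strands.

    direction +1 means the element reads left-to-right at that site.
    Overlapping hits are collapsed to the best per 50 bp.
    """
    sites: list[tuple[int, int]] = []
    for query, direction in ((guide, 1), (revcomp(guide), -1)):
        # edlib reports only minimum-distance locations, so mask each hit
        # and re-align until nothing within max_dist remains
        text = seq
        found: list[int] = []
        for _ in range(200):
            res = edlib.align(query, text, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0 or not res["locations"]:
                break
            starts = []
            for loc in res["locations"]:
                start, end = loc
                if start is None:
                    start = end - len(query) + 1
                starts.append(start)
            starts = sorted(set(starts))
            kept, last = [], -(10**9)
            for s in starts:
                if s - last >= 50:
                    kept.append(s)
                    last = s
            found.extend(kept)
            chars = list(text)
            for s in kept:
                chars[max(0, s - 5) : s + len(query) + 5] = "#" * (
                    min(len(text), s + len(query) + 5) - max(0, s - 5)
                )
            text = "".join(chars)
        kept, last = [], -(10**9)
        for s in sorted(found):
            if s - last < 50:
                continue
            last = s
            # edlib may report a start off by one when a gap ties with a
            # substitution; refine by ungapped Hamming placement
            best_s, best_d = s, 10**9
            for s2 in range(max(0, s - 2), min(len(seq) - len(query), s + 2) + 1):
                window = seq[s2 : s2 + len(query)]
                d = sum(a != b for a, b in zip(query, window))
                if d < best_d:
                    best_s, best_d = s2, d
            pam_n = best_s + 20 if direction == 1 else best_s + 2
            sites.append((pam_n, direction))
    return sorted(sites)


def simulate_cas9_run(
    truth: TruthSet,
    guide: str,
    run_id: str = "run0",
    seed_stream: int = 2,
) -> SimRun:
    """Cas9-cut reads from every guide-matched site on each haplotype.

    Reads start at a cut offset sampled from the configured distribution
    (forward: offsets 3-4 from the NGG PAM; reverse: offset 7) and extend
    bi-directionally from the cleavage site with the configured strand
    bias; uniform background reads are added on top.
    """
    config = truth.config
    rc = config.reads
    rng = np.random.default_rng([config.seed, seed_stream])
    reads: list[QualityRead] = []
    alns: list[AlignmentRecord] = []
    prov: list[ReadProvenance] = []
    n_on = 0

    site_lists = []
    for hap in (0, 1):
        sites = find_guide_sites(guide, truth.haplotypes[hap])
        if not sites:
            raise ValueError("guide matches no site on haplotype %d" % hap)
        site_lists.append(sites)

    # locate each site's locus for provenance
    def locus_of(hap: int, pos: int) -> Optional[str]:
        # inside an I segment -> a non-reference locus; else a reference copy
        for hs, he, kind, rs in _hap_segments(truth, hap):
            if hs <= pos < he:
                if kind == "I":
                    for loc in truth.loci:
                        if hap in loc.haplotypes and loc.position == rs:
                            return loc.locus_id
                else:
                    ref_pos = rs + (pos - hs)
                    for f in truth.features:
                        if f.start <= ref_pos < f.end:
                            return f"{f.subfamily}:{f.start}"
                return None
        return None

    p_fwd = rc.strand_bias / (1.0 + rc.strand_bias)
    idx = 0
    for hap in (0, 1):
        segs = _hap_segments(truth, hap)
        for pam_n, direction in site_lists[hap]:
            n_reads = rng.poisson(rc.reads_per_cut) if rc.poisson else int(rc.reads_per_cut)
            lid = locus_of(hap, pam_n)
            for _ in range(n_reads):
                frame_fwd = rng.random() < p_fwd
                dist = rc.cut_offsets_fwd if frame_fwd else rc.cut_offsets_rev
                d = _sample_offset(rng, dist)
                start = pam_n - direction * d
                L = _read_length(rng, rc)
                extend = direction if frame_fwd else -direction
                if extend == 1:
                    a, b, orient = start, start + L, "+"
                else:
                    a, b, orient = start - L + 1, start + 1, "-"
                qual = 4 if rng.random() < rc.low_q_fraction else int(
                    np.clip(rng.normal(rc.mean_q, 2.0), 8, 30)
                )
                name = f"{run_id}_r{idx:05d}"
                idx += 1
                read, aln = _make_read(truth, segs, hap, a, b, orient, name, rng, rc, qual)
                reads.append(read)
                if aln is not None:
                    alns.append(aln)
                prov.append(
                    ReadProvenance(name, hap, lid, "fwd" if frame_fwd else "rev", d, aln is not None)
                )
                n_on += 1

    n_bg = int(n_on * rc.background_fraction / max(1e-9, 1 - rc.background_fraction))
    for _ in range(n_bg):
        hap = int(rng.integers(0, 2))
        segs = _hap_segments(truth, hap)
        L = _read_length(rng, rc)
        a = int(rng.integers(0, max(1, len(truth.haplotypes[hap]) - L)))
        orient = "+" if rng.random() < 0.5 else "-"
        qual = 4 if rng.random() < rc.low_q_fraction else int(np.clip(rng.normal(rc.mean_q, 2.0), 8, 30))
        name = f"{run_id}_r{idx:05d}"
        idx += 1
        read, aln = _make_read(truth, segs, hap, a, a + L, orient, name, rng, rc, qual)
        reads.append(read)
        if aln is not None:
            alns.append(aln)
        prov.append(ReadProvenance(name, hap, None, "bg", -1, aln is not None))

    manifest = {
        "run_id": run_id,
        "seed": config.seed,
        "guide": guide,
        "n_reads": len(reads),
        "n_cut_reads": n_on,
        "n_background": n_bg,
        "sites_per_hap": [len(s) for s in site_lists],
    }
    return SimRun(reads, alns, prov, manifest)


def simulate_wgs_run(truth: TruthSet, run_id: str = "wgs0", depth: float = 20.0, seed_stream: int = 3) -> SimRun:
    """Uniform-coverage run over both haplotypes (whole-genome baseline)."""
    config = truth.config
    rc = config.reads
    rng = np.random.default_rng([config.seed, seed_stream])
    mean_len = float(np.exp(np.log(rc.n50) - rc.sigma**2 + rc.sigma**2 / 2))
    reads: list[QualityRead] = []
    alns: list[AlignmentRecord] = []
    prov: list[ReadProvenance] = []
    idx = 0
    for hap in (0, 1):
        hap_len = len(truth.haplotypes[hap])
        segs = _hap_segments(truth, hap)
        n = int(depth / 2 * hap_len / mean_len)
        for _ in range(n):
            L = _read_length(rng, rc)
            a = int(rng.integers(-L + rc.min_len, hap_len - rc.min_len))
            orient = "+" if rng.random() < 0.5 else "-"
            qual = int(np.clip(rng.normal(rc.mean_q, 2.0), 8, 30))
            name = f"{run_id}_r{idx:05d}"
            idx += 1
            read, aln = _make_read(truth, segs, hap, a, a + L, orient, name, rng, rc, qual)
            reads.append(read)
            if aln is not None:
                alns.append(aln)
            prov.append(ReadProvenance(name, hap, None, "bg", -1, aln is not None))
    manifest = {"run_id": run_id, "seed": config.seed, "depth": depth, "n_reads": len(reads)}
    return SimRun(reads, alns, prov, manifest)


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_run(outdir: str | Path, truth: TruthSet, run: SimRun) -> None:
    """Emit reference.fa, annotation (BED + .out), donor FASTAs, reads, truth PAF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fa", [truth.genome])
    write_repeat_annotation(outdir / "annotation.bed", truth.features, "bed")
    write_repeat_annotation(outdir / "annotation.out", truth.features, "rmout")
    for i in (0, 1):
        write_fasta(outdir / f"donor_h{i + 1}.fa", [SequenceRecord(f"hap{i + 1}", truth.haplotypes[i], "genome")])
    write_fasta(outdir / "consensus.fa", list(truth.consensus.values()))
    write_fastq(outdir / "reads.fastq", run.reads)
    write_paf(outdir / "truth.paf", run.alignments, {truth.genome.id: len(truth.genome.seq)})
    with open(outdir / "truth_loci.tsv", "w") as fh:
        fh.write("locus_id\tposition\tsubfamily\tstrand\telement_len\tpolya_len\ttsd\tzygosity\tinverted5\n")
        for loc in truth.loci:
            fh.write(
                f"{loc.locus_id}\t{loc.position}\t{loc.subfamily}\t{loc.strand}\t"
                f"{loc.element_len}\t{loc.polya_len}\t{loc.tsd}\t{loc.zygosity}\t{int(loc.inverted5)}\n"
            )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=1)
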