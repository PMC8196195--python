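"""Readers/writers and the shared coordinate convention.

Every module in this package uses 0-based half-open coordinates internally;
1-based dialects (RepeatMasker .out, SAM POS) are converted at the I/O
boundary and nowhere else.

CIGAR convention: the CIGAR is stored in reference order and consumes the
read in its *aligned* orientation (for ``strand == '-'`` that is the reverse
complement of the stored sequence).  Soft/hard clips sit at the CIGAR ends;
hard clips contribute to ``read_len`` but not to any stored sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "QualityRead",
    "AlignmentRecord",
    "RepeatFeature",
    "Hallmarks",
    "MEICallRecord",
    "ParseError",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_repeat_annotation",
    "write_repeat_annotation",
    "read_alignments",
    "write_paf",
    "read_calls",
    "write_calls",
    "parse_cigar",
    "cigar_string",
    "cigar_read_span",
    "cigar_ref_span",
]


class ParseError(ValueError):
    """Raised when an on-disk record cannot be interpreted."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")

READ_CONSUMING = frozenset("M=XIS")
REF_CONSUMING = frozenset("M=XD")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_seq(seq: str, *, context: str = "") -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ParseError(f"empty sequence {context}".strip())
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ParseError(f"invalid characters {bad} {context}".strip())
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

Role = Literal["target_consensus", "outgroup_consensus", "genome", "read"]


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    role: Role = "genome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean_seq(self.seq, context=f"in record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred scores.

    ``mean_q`` averages on the error-probability scale (10^(-Q/10)) and
    converts back, matching common base-caller run summaries.
    """

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean_seq(self.seq, context=f"in read {self.id!r}"))
        object.__setattr__(self, "quals", tuple(int(q) for q in self.quals))
        if len(self.quals) != len(self.seq):
            raise ParseError(f"read {self.id!r}: {len(self.quals)} quals for {len(self.seq)} bases")

    @property
    def mean_q(self) -> float:
        p = np.power(10.0, -np.asarray(self.quals, dtype=float) / 10.0)
        return float(-10.0 * np.log10(p.mean()))

    def __len__(self) -> int:
        return len(self.seq)


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar))
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ParseError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_string(ops: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def cigar_read_span(ops: Iterable[tuple[str, int]], *, include_clips: bool = False) -> int:
    consuming = READ_CONSUMING | {"H"} if include_clips else frozenset("M=XI")
    return sum(n for op, n in ops if op in consuming)


def cigar_ref_span(ops: Iterable[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in REF_CONSUMING)


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment (PAF-equivalent fields plus CIGAR)."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    ref_name: str
    ref_start: int
    ref_end: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"{self.read_id}: bad strand {self.strand!r}")
        if not (0 <= self.read_start <= self.read_end <= self.read_len):
            raise ParseError(f"{self.read_id}: read interval out of bounds")
        if self.ref_start >= self.ref_end:
            raise ParseError(f"{self.read_id}: empty reference span")
        if not (0 <= self.mapq <= 60):
            raise ParseError(f"{self.read_id}: MAPQ {self.mapq} outside 0-60")
        aligned = sum(n for op, n in self.cigar if op in "M=XI")
        if aligned != self.read_end - self.read_start:
            raise ParseError(
                f"{self.read_id}: CIGAR consumes {aligned} read bases, "
                f"interval is {self.read_end - self.read_start}"
            )
        total = cigar_read_span(self.cigar, include_clips=True)
        if total != self.read_len:
            raise ParseError(f"{self.read_id}: CIGAR+clips {total} != read_len {self.read_len}")
        ref = cigar_ref_span(self.cigar)
        if ref != self.ref_end - self.ref_start:
            raise ParseError(
                f"{self.read_id}: CIGAR consumes {ref} ref bases, span is "
                f"{self.ref_end - self.ref_start}"
            )

    def aligned_read_seq(self, seq: str) -> str:
        """Read sequence in the orientation the CIGAR walks it."""
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class RepeatFeature:
    ref_name: str
    start: int
    end: int
    strand: str
    family: str
    subfamily: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(f"repeat {self.subfamily} at {self.ref_name}: start >= end")


@dataclass
class Hallmarks:
    """TPRT signatures attached to a non-reference MEI call."""

    tsd: Optional[str] = None
    polya_len: int = 0
    en_site_score: int = 0
    transduction_seq: Optional[str] = None
    inverted5: bool = False
    empty_site_ok: bool = False


@dataclass
class MEICallRecord:
    ref_name: str
    position: int
    subfamily: str
    strand: str
    length: int
    support: int
    genotype: str = "unknown"
    hallmarks: Hallmarks = field(default_factory=Hallmarks)
    status: str = "non_reference"
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ParseError("MEI call with support < 1")
        if self.length < 0:
            raise ParseError("MEI call with negative length")


# ---------------------------------------------------------------------------
# Subfamily taxonomy
# ---------------------------------------------------------------------------

#: Packaged subfamily -> family table.  Prefix rules handle numbered
#: RepeatMasker names (L1PA4, AluYb8, ...) not listed literally.
SUBFAMILY_FAMILY: dict[str, str] = {
    "L1Hs": "L1", "L1HS": "L1", "L1Ta": "L1", "L1PreTa": "L1",
    "L1PA2": "L1", "L1PA3": "L1", "L1PA4": "L1", "L1PB": "L1", "L1M": "L1",
    "AluY": "Alu", "AluYa5": "Alu", "AluYa8": "Alu", "AluYb8": "Alu",
    "AluYb9": "Alu", "AluSx": "Alu", "AluJr": "Alu", "AluJb": "Alu",
    "SVA_A": "SVA", "SVA_B": "SVA", "SVA_C": "SVA", "SVA_D": "SVA",
    "SVA_E": "SVA", "SVA_F": "SVA",
}


def family_of(subfamily: str) -> str:
    if subfamily in SUBFAMILY_FAMILY:
        return SUBFAMILY_FAMILY[subfamily]
    for prefix, fam in (("L1", "L1"), ("Alu", "Alu"), ("SVA", "SVA"), ("FLAM", "Alu"), ("FRAM", "Alu")):
        if subfamily.startswith(prefix):
            return fam
    return subfamily


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, role: Role = "genome") -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), role))
    return records


def write_fasta(path: str | Path, records: Sequence[SequenceRecord], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[QualityRead]:
    reads: list[QualityRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTQ id {rec.id!r} in {path}")
        seen.add(rec.id)
        reads.append(QualityRead(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])))
    return reads


def write_fastq(path: str | Path, reads: Sequence[QualityRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# Repeat annotation (RepeatMasker .out and BED6)
# ---------------------------------------------------------------------------

def read_repeat_annotation(path: str | Path, dialect: str = "bed") -> list[RepeatFeature]:
    """Load a repeat annotation.

    ``rmout`` rows carry 1-based inclusive coordinates which are converted to
    the internal 0-based half-open convention; BED6 rows pass through.  The
    subfamily comes from the repeat-name column and the family from the
    packaged taxonomy table (the .out class/family column is ignored so both
    dialects behave identically).
    """
    feats: list[RepeatFeature] = []
    if dialect == "bed":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: BED row needs >=4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            feats.append(RepeatFeature(chrom, start, end, strand, family_of(name), name))
    elif dialect == "rmout":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.lower().startswith(("sw", "score", "there were no")):
                continue
            parts = s.split()
            if len(parts) < 11 or not parts[0].replace(".", "").isdigit():
                continue
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            name = parts[9]
            start0 = begin - 1  # 1-based inclusive -> 0-based half-open
            if start0 >= end:
                raise ParseError(f"{path}:{ln}: empty interval after conversion")
            feats.append(RepeatFeature(chrom, start0, end, strand, family_of(name), name))
    else:
        raise ParseError(f"unknown repeat annotation dialect {dialect!r}")
    return feats


def write_repeat_annotation(path: str | Path, feats: Sequence[RepeatFeature], dialect: str = "bed") -> None:
    with open(path, "w") as fh:
        if dialect == "bed":
            for f in feats:
                fh.write(f"{f.ref_name}\t{f.start}\t{f.end}\t{f.subfamily}\t0\t{f.strand}\n")
        elif dialect == "rmout":
            fh.write("   SW  perc perc perc  query     position in query     matching  repeat\n\n")
            for i, f in enumerate(feats, 1):
                strand = "C" if f.strand == "-" else "+"
                fh.write(
                    f"  225  10.0  0.0  0.0  {f.ref_name} {f.start + 1} {f.end} (0) "
                    f"{strand} {f.subfamily} {f.family} 1 {f.end - f.start} (0) {i}\n"
                )
        else:
            raise ParseError(f"unknown repeat annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Alignments (PAF with cg: tag; SAM text via pysam)
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, format: str = "paf") -> tuple[list[AlignmentRecord], int]:
    """Parse read-to-reference alignments.

    Returns ``(records, n_rejected)``: rows violating the CIGAR bookkeeping
    invariants are dropped and counted rather than raising.
    """
    if format == "paf":
        return _read_paf(path)
    if format == "sam":
        return _read_sam(path)
    raise ParseError(f"unknown alignment format {format!r}")


def _read_paf(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    records: list[AlignmentRecord] = []
    rejected = 0
    missing_cigar: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ParseError(f"PAF row with {len(parts)} columns")
        cg = next((p[5:] for p in parts[12:] if p.startswith("cg:Z:")), None)
        if cg is None:
            missing_cigar.append(parts[0])
            continue
        rec = AlignmentRecord(
            read_id=parts[0],
            read_len=int(parts[1]),
            read_start=int(parts[2]),
            read_end=int(parts[3]),
            strand=parts[4],
            ref_name=parts[5],
            ref_start=int(parts[7]),
            ref_end=int(parts[8]),
            mapq=int(parts[11]),
            cigar=_pad_clips(parse_cigar(cg), int(parts[2]), int(parts[1]) - int(parts[3]), parts[4]),
        )
        try:
            rec.validate()
        except ParseError:
            rejected += 1
            continue
        records.append(rec)
    if missing_cigar:
        raise ParseError(f"PAF rows missing cg:Z: CIGAR for reads: {', '.join(missing_cigar)}")
    return records, rejected


def _pad_clips(ops: tuple[tuple[str, int], ...], head: int, tail: int, strand: str) -> tuple[tuple[str, int], ...]:
    """PAF CIGARs omit clips; reconstruct them from the query interval.

    PAF query coordinates are on the original read; the CIGAR walks the
    aligned orientation, so head/tail swap on the minus strand.
    """
    if strand == "-":
        head, tail = tail, head
    out = list(ops)
    if out and out[0][0] not in "SH" and head:
        out.insert(0, ("S", head))
    if out and out[-1][0] not in "SH" and tail:
        out.append(("S", tail))
    return tuple(out)


def _read_sam(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    import pysam

    records: list[AlignmentRecord] = []
    rejected = 0
    missing: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            if seg.cigartuples is None:
                missing.append(seg.query_name)
                continue
            ops = tuple(("MIDNSHP=XB"[op], n) for op, n in seg.cigartuples)
            read_len = cigar_read_span(ops, include_clips=True)
            head = sum(n for op, n in (ops[0],) if op in "SH") if ops[0][0] in "SH" else 0
            tail = sum(n for op, n in (ops[-1],) if op in "SH") if ops[-1][0] in "SH" else 0
            strand = "-" if seg.is_reverse else "+"
            # CIGAR walks the aligned orientation; report read coords on the
            # original read.
            if strand == "+":
                read_start, read_end = head, read_len - tail
            else:
                read_start, read_end = tail, read_len - head
            rec = AlignmentRecord(
                read_id=seg.query_name,
                read_len=read_len,
                read_start=read_start,
                read_end=read_end,
                strand=strand,
                ref_name=seg.reference_name,
                ref_start=seg.reference_start,
                ref_end=seg.reference_end,
                mapq=seg.mapping_quality,
                cigar=ops,
            )
            try:
                rec.validate()
            except ParseError:
                rejected += 1
                continue
            records.append(rec)
    if missing:
        raise ParseError(f"SAM records missing CIGAR for reads: {', '.join(missing)}")
    return records, rejected


def write_paf(path: str | Path, records: Sequence[AlignmentRecord], ref_lens: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for r in records:
            core = tuple(op for op in r.cigar if op[0] not in "SH")
            matches = sum(n for op, n in core if op in "M=")
            block = sum(n for _, n in core)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id, r.read_len, r.read_start, r.read_end, r.strand,
                        r.ref_name, ref_lens[r.ref_name], r.ref_start, r.ref_end,
                        matches, block, r.mapq,
                    )
                )
                + f"\tcg:Z:{cigar_string(core)}\n"
            )


# ---------------------------------------------------------------------------
# Callset TSV
# ---------------------------------------------------------------------------

CALL_COLUMNS = (
    "chrom", "pos", "subfamily", "strand", "length", "support", "genotype",
    "tsd", "polya_len", "en_matches", "inverted5", "transduction", "status", "filter",
)


def write_calls(path: str | Path, calls: Sequence[MEICallRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            h = c.hallmarks
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.ref_name, c.position, c.subfamily, c.strand, c.length,
                        c.support, c.genotype, h.tsd or ".", h.polya_len,
                        h.en_site_score, int(h.inverted5), h.transduction_seq or ".",
                        c.status, c.filter,
                    )
                )
                + "\n"
            )


def read_calls(path: str | Path) -> list[MEICallRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != CALL_COLUMNS:
        raise ParseError(f"{path}: unexpected callset header")
    calls = []
    for line in lines[1:]:
        if not line.strip():
            continue
        v = line.split("\t")
        calls.append(
            MEICallRecord(
                ref_name=v[0], position=int(v[1]), subfamily=v[2], strand=v[3],
                length=int(v[4]), support=int(v[5]), genotype=v[6],
                hallmarks=Hallmarks(
                    tsd=None if v[7] == "." else v[7],
                    polya_len=int(v[8]),
                    en_site_score=int(v[9]),
                    inverted5=bool(int(v[10])),
                    transduction_seq=None if v[11] == "." else v[11],
                ),
                status=v[12], filter=v[13],
            )
        )
    return calls
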