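"""End-to-end orchestration of one enrichment run.

Wires the front end (quality filter, pre-masking, optional end-scan,
classification) to the caller and tallies per-locus support, so the
depth-ratio and rate analyses can run off a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .meicaller import (
    CallerParams,
    InsertionSignal,
    MEICallRecord,
    call_nonreference,
    extract_insertion_signals,
)
from .readclass import (
    MEISignal,
    ReadClassification,
    TargetRateTable,
    classify_read,
    filter_reads,
    project_annotation_to_read,
    scan_read_for_mei,
    tally_target_rates,
)
from .seqio import (
    AlignmentRecord,
    QualityRead,
    RepeatFeature,
    SequenceRecord,
)

__all__ = ["RunResult", "run_pipeline"]


@dataclass
class RunResult:
    classifications: list[ReadClassification]
    calls: list[MEICallRecord]
    ins_signals: list[InsertionSignal]
    scan_signals: dict[str, MEISignal] = field(default_factory=dict)
    ref_support: dict[tuple[str, int], int] = field(default_factory=dict)
    rates: Optional[TargetRateTable] = None

    @property
    def nonref_calls(self) -> list[MEICallRecord]:
        return [c for c in self.calls if c.status == "non_reference"]


def run_pipeline(
    reads: Sequence[QualityRead],
    alns: Sequence[AlignmentRecord],
    features: Sequence[RepeatFeature],
    consensus_lib: Sequence[SequenceRecord],
    experiment_subfamily: str,
    genome: Optional[SequenceRecord] = None,
    params: CallerParams = CallerParams(),
    scan: bool = False,
    run_id: str = "run",
) -> RunResult:
    """Classify every read and call non-reference MEIs for one run.

    ``scan=False`` skips the terminal-bin consensus scan (only needed for
    signal-location summaries and the SVA off-target rule); classification
    by mapping position and pre-masking hits is unaffected.
    """
    kept, dropped = filter_reads(reads, params.min_q)
    seqs = {r.id: r.seq for r in kept}
    primary: dict[str, AlignmentRecord] = {}
    for a in alns:
        if a.read_id in seqs and a.read_id not in primary:
            primary[a.read_id] = a

    mei_families = {"L1", "Alu", "SVA"}
    target_feats = [f for f in features]
    classifications: list[ReadClassification] = []
    scan_signals: dict[str, MEISignal] = {}
    all_signals: list[InsertionSignal] = []
    ref_support: dict[tuple[str, int], int] = {}

    for r in dropped:
        classifications.append(ReadClassification(r.id, "discarded_quality", "mean Q below threshold"))

    for r in kept:
        aln = primary.get(r.id)
        sigs: list[InsertionSignal] = []
        masked = None
        if aln is not None and aln.mapq >= params.min_mapq:
            masked = project_annotation_to_read(aln, features, mei_families)
            sigs = extract_insertion_signals(aln, r.seq, masked, genome, params)
            all_signals.extend(sigs)
        signal = None
        if scan:
            signal = scan_read_for_mei(r, consensus_lib)
            scan_signals[r.id] = signal
        cls = classify_read(
            r, aln, signal, masked, palmer_hit=bool(sigs),
            experiment_subfamily=experiment_subfamily, features=target_feats,
            min_mapq=params.min_mapq,
        )
        classifications.append(cls)
        if cls.category == "on_target_reference" and aln is not None:
            best, key = 0, None
            for f in features:
                if f.subfamily != experiment_subfamily or f.ref_name != aln.ref_name:
                    continue
                ov = min(aln.ref_end, f.end) - max(aln.ref_start, f.start)
                if ov > best:
                    best, key = ov, (f.ref_name, f.start)
            if key is not None:
                ref_support[key] = ref_support.get(key, 0) + 1

    calls = call_nonreference(reads, alns, features, consensus_lib, genome, params)
    rates = tally_target_rates(
        classifications,
        scan_signals if scan else None,
        {r.id: len(r.seq) for r in kept} if scan else None,
        run=run_id,
        subfamily=experiment_subfamily,
    )
    return RunResult(classifications, calls, all_signals, scan_signals, ref_support, rates)
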