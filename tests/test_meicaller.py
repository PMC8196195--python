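"""Signal extraction, TPRT hallmarks, clustering, genotyping, calling."""

import statistics

import numpy as np
import pytest

from nanomei import meicaller as mc
from nanomei.meicaller import call_nonreference
from nanomei.readclass import MaskedRead
from nanomei.seqio import AlignmentRecord, cigar_ref_span, revcomp


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _aln(cigar, read_len, ref_start=1000, strand="+", read_id="r"):
    aligned = sum(n for op, n in cigar if op in "M=XI")
    lead = cigar[0][1] if cigar[0][0] in "SH" else 0
    tail = cigar[-1][1] if cigar[-1][0] in "SH" else 0
    rs, re_ = (lead, read_len - tail) if strand == "+" else (tail, read_len - lead)
    a = AlignmentRecord(read_id, read_len, rs, re_, strand, "chr1", ref_start,
                        ref_start + cigar_ref_span(cigar), 60, tuple(cigar))
    a.validate()
    return a


class TestSignalExtraction:
    def test_cigar_insertion(self):
        rng = np.random.default_rng(0)
        seq = _rand(rng, 700)
        a = _aln([("M", 100), ("I", 500), ("M", 100)], 700)
        (s,) = mc.extract_insertion_signals(a, seq)
        assert s.source == "cigar_insertion"
        assert s.breakpoint == 1100
        assert s.ins_seq == seq[100:600]
        assert s.read_interval == (100, 600)

    def test_plain_match_yields_nothing(self):
        a = _aln([("M", 200)], 200)
        assert mc.extract_insertion_signals(a, "A" * 200) == []

    def test_terminal_soft_clip(self):
        rng = np.random.default_rng(1)
        seq = _rand(rng, 500)
        a = _aln([("S", 300), ("M", 200)], 500)
        (s,) = mc.extract_insertion_signals(a, seq)
        assert s.source == "soft_clip" and s.clip_side == "left"
        assert s.breakpoint == 1000
        assert s.ins_seq == seq[:300]

    def test_short_events_filtered(self):
        a = _aln([("S", 100), ("M", 100), ("I", 50), ("M", 100)], 350)
        assert mc.extract_insertion_signals(a, "A" * 350) == []

    def test_masked_insertion_suppressed(self):
        seq = "A" * 700
        a = _aln([("M", 100), ("I", 500), ("M", 100)], 700)
        masked = MaskedRead("r", 700, ((100, 600),))
        assert mc.extract_insertion_signals(a, seq, masked) == []

    def test_minus_strand_read_interval_is_on_original_read(self):
        rng = np.random.default_rng(2)
        seq = _rand(rng, 500)
        a = _aln([("S", 300), ("M", 200)], 500, strand="-")
        (s,) = mc.extract_insertion_signals(a, seq)
        # aligned-orientation clip (0,300) maps to (200,500) on the read
        assert s.read_interval == (200, 500)
        assert s.ins_seq == revcomp(seq)[:300]


class TestTSD:
    def test_implanted_word_recovered_exactly(self):
        rng = np.random.default_rng(3)
        tsd = _rand(rng, 12)
        element = "C" + _rand(rng, 200) + "G"
        flank3 = tsd + "T" + _rand(rng, 30)  # junction base differs from element[0]
        ins = tsd + element + "A" * 20
        assert mc.detect_tsd(ins, "", flank3) == tsd

    def test_random_flanks_give_none(self):
        rng = np.random.default_rng(4)
        assert mc.detect_tsd(_rand(rng, 60), _rand(rng, 50), _rand(rng, 50)) is None

    def test_one_substitution_tolerated(self):
        rng = np.random.default_rng(5)
        tsd = "ACGTACGT"
        mutated = "ACGAACGT"  # one substitution, ends still match
        ins = mutated + "C" + _rand(rng, 100)
        flank3 = tsd + "G" + _rand(rng, 30)
        got = mc.detect_tsd(ins, "", flank3, max_mismatch=1)
        assert got == mutated

    def test_right_aligned_insertion_suffix_route(self):
        rng = np.random.default_rng(6)
        tsd = _rand(rng, 10)
        flank5 = _rand(rng, 30) + tsd
        ins = "C" + _rand(rng, 150) + "AAAAAAAAAA" + tsd
        assert mc.detect_tsd(ins, flank5, "") == tsd


class TestPolyA:
    def test_long_terminal_run(self):
        assert mc.detect_polya("GCGC" + "A" * 30) == 30

    def test_below_min_len(self):
        assert mc.detect_polya("GCGCGCGC" + "A" * 9) == 0

    def test_interrupted_tract_scanning_oracle(self):
        assert mc.detect_polya("CCGGCC" + "A" * 12 + "G" + "A" * 12, purity=0.8) == 25

    def test_minus_strand_scans_five_prime_t_tract(self):
        assert mc.detect_polya("T" * 25 + "GCGGCC", strand="-") == 25


class TestENMotif:
    @pytest.mark.parametrize(
        "window,expected",
        [("TTTTAA", 6), ("GGGGGG", 0), ("TTTAAA", 5), ("TTTTAC", 5)],
    )
    def test_positionwise_matches(self, window, expected):
        assert mc.detect_en_motif(window) == expected

    def test_centered_window(self):
        assert mc.detect_en_motif("GGGG" + "TTTTAA" + "GGGG", break_index=8) == 6


class TestClustering:
    def _sig(self, read_id, pos, n=150):
        return mc.InsertionSignal(read_id, "chr1", pos, "cigar_insertion", "A" * n, (0, n))

    def test_tight_group_is_one_call(self):
        sigs = [self._sig(f"r{i}", 1000 + 10 * i) for i in range(5)]
        (cl,) = mc.cluster_supporting_reads(sigs, min_support=4)
        assert cl.support == 5
        assert cl.position == statistics.median(s.breakpoint for s in sigs)

    def test_below_min_support_not_reported(self):
        sigs = [self._sig(f"r{i}", 1000) for i in range(3)]
        assert mc.cluster_supporting_reads(sigs, min_support=4) == []

    def test_distant_groups_split(self):
        sigs = [self._sig(f"a{i}", 1000) for i in range(4)] + [self._sig(f"b{i}", 2500) for i in range(4)]
        assert len(mc.cluster_supporting_reads(sigs, min_support=4)) == 2

    def test_one_signal_per_read(self):
        sigs = [self._sig("same", 1000, n) for n in (100, 200)] + [
            self._sig(f"r{i}", 1010) for i in range(3)
        ]
        (cl,) = mc.cluster_supporting_reads(sigs, min_support=4)
        assert cl.support == 4  # the duplicated read counts once


class TestGenotype:
    @pytest.mark.parametrize("support,span,expected", [(10, 10, "hom"), (5, 10, "het"), (1, 10, "unknown")])
    def test_rule(self, support, span, expected):
        assert mc.genotype_call(support, span) == expected

    def test_zero_span_is_an_error(self):
        with pytest.raises(ValueError):
            mc.genotype_call(1, 0)


class TestDepthFilter:
    def _coverage(self, center_depth, flank_depth=10, bins=5, bin_bp=100):
        cov = []
        for b in range(bins):
            cov += [center_depth if b == bins // 2 else flank_depth] * bin_bp
        return cov

    def test_high_pileup_fails(self):
        ok, reason = mc.apply_depth_filter(250, self._coverage(25), bin_bp=100)
        assert not ok

    def test_modest_difference_passes(self):
        ok, _ = mc.apply_depth_filter(250, self._coverage(12), bin_bp=100)
        assert ok

    def test_exactly_twofold_fails(self):
        ok, _ = mc.apply_depth_filter(250, self._coverage(20), bin_bp=100)
        assert not ok

    def test_zero_flank_coverage(self):
        ok, reason = mc.apply_depth_filter(250, self._coverage(10, flank_depth=0), bin_bp=100)
        assert not ok and reason == "no_flank_coverage"


class TestAssignSubfamily:
    def test_diagnostic_insertion_identifies_aluyb(self, toy_lib):
        lib = list(toy_lib.values())
        fam, sub, strand, inv = mc.assign_subfamily(toy_lib["AluYb8"].seq, lib)
        assert (fam, sub, strand, inv) == ("Alu", "AluYb8", "+", False)
        assert "CAGTCCG" in toy_lib["AluYb8"].seq

    def test_reverse_complement_flips_strand_only(self, toy_lib):
        lib = list(toy_lib.values())
        fam, sub, strand, _ = mc.assign_subfamily(revcomp(toy_lib["SVA_F"].seq), lib)
        assert (sub, strand) == ("SVA_F", "-")

    def test_twin_priming_signature(self, toy_lib):
        lib = list(toy_lib.values())
        el = toy_lib["L1Hs"].seq[-2000:]
        twin = revcomp(el[:900]) + el[900:]
        fam, sub, strand, inv = mc.assign_subfamily(twin, lib)
        assert sub == "L1Hs" and inv and strand == "+"

    def test_unalignable_sequence_is_unknown(self, toy_lib):
        rng = np.random.default_rng(11)
        fam, sub, _, _ = mc.assign_subfamily(_rand(rng, 40), list(toy_lib.values()))
        assert (fam, sub) == ("unknown", "unknown")


def _match_truth(calls, loci, window=100):
    hits = {}
    for c in calls:
        for l in loci:
            if abs(c.position - l.position) <= window:
                hits[l.locus_id] = c
    return hits


class TestRoundTrip:
    def test_error_free_recall_and_precision(self, clean_run, toy_lib):
        truth, run = clean_run
        lib = list(toy_lib.values())
        calls = call_nonreference(run.reads, run.alignments, truth.features, lib, truth.genome)
        nonref = [c for c in calls if c.status == "non_reference"]
        hits = _match_truth(nonref, truth.loci)
        assert len(hits) == len(truth.loci)          # 100% recall
        assert len(nonref) == len(truth.loci)        # 100% precision
        for c in nonref:
            assert c.support >= 4
            assert c.subfamily == "L1Hs"

    def test_no_implants_no_calls(self, toy_lib):
        from tests.conftest import build, small_l1_config

        truth, run = build(small_l1_config(23, error_free=True, count=0))
        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_lib.values()), truth.genome)
        assert [c for c in calls if c.status == "non_reference"] == []

    def test_support_threshold_suppresses_thin_loci(self):
        from tests.conftest import build, small_l1_config

        config = small_l1_config(29, error_free=True, min_len=700)
        config.reads.reads_per_cut = 3.0  # het loci get 3 reads: below min 4
        config.nonref.het_fraction = 1.0
        config.reads.background_fraction = 0.0
        truth, run = build(config)
        from nanomei.simforge import toy_consensus_library

        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_consensus_library().values()), truth.genome)
        assert [c for c in calls if c.status == "non_reference"] == []

    def test_strand_and_length_annotation(self, clean_run, toy_lib):
        truth, run = clean_run
        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_lib.values()), truth.genome)
        by_truth = _match_truth([c for c in calls if c.status == "non_reference"], truth.loci)
        agree = sum(1 for lid, c in by_truth.items()
                    if c.strand == next(l.strand for l in truth.loci if l.locus_id == lid))
        assert agree >= 0.9 * len(by_truth)


class TestHallmarkRoundTrip:
    def test_tsd_and_polya_exact_on_error_free_spanning_reads(self, wgs_run, toy_lib):
        truth, run = wgs_run
        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_lib.values()), truth.genome)
        nonref = [c for c in calls if c.status == "non_reference"]
        hits = _match_truth(nonref, truth.loci)
        assert len(hits) >= 0.9 * len(truth.loci)
        for lid, call in hits.items():
            locus = next(l for l in truth.loci if l.locus_id == lid)
            assert call.hallmarks.tsd == locus.tsd
            assert call.hallmarks.polya_len == locus.polya_len

    def test_genotype_concordance_at_uniform_depth(self, wgs_run, toy_lib):
        truth, run = wgs_run
        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_lib.values()), truth.genome)
        hits = _match_truth([c for c in calls if c.status == "non_reference"], truth.loci)
        agree = sum(
            1 for lid, c in hits.items()
            if c.genotype == next(l.zygosity for l in truth.loci if l.locus_id == lid)
        )
        assert agree >= 0.9 * len(hits)


class TestInversionDetection:
    def test_all_loci_inverted_when_probability_is_one(self, toy_lib):
        from tests.conftest import build, small_l1_config

        config = small_l1_config(31, error_free=True, min_len=900, inversion_prob=1.0)
        truth, run = build(config)
        assert all(l.inverted5 for l in truth.loci)
        calls = call_nonreference(run.reads, run.alignments, truth.features,
                                  list(toy_lib.values()), truth.genome)
        nonref = [c for c in calls if c.status == "non_reference"]
        flagged = sum(1 for c in nonref if c.hallmarks.inverted5)
        assert flagged >= 0.6 * len(nonref)
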