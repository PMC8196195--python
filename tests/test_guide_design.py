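"""Guide design: diagnostics, PAM windows, k-mer counting, tiers, bounds."""

import numpy as np
import pytest

from nanomei import guide_design as gd
from nanomei.seqio import RepeatFeature, SequenceRecord, revcomp
from nanomei.simforge import TOY_GUIDE_SITES, toy_guide


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDiagnosticPositions:
    def test_single_difference(self):
        prof = gd.diagnostic_positions("ACGT", ["ACGA"], aligned=True)
        assert prof.positions == (3,)

    def test_identical_sequences(self):
        assert gd.diagnostic_positions("ACGT", ["ACGT"], aligned=True).positions == ()

    def test_column_must_differ_from_every_outgroup(self):
        # brute-force check: only position 3 differs from both outgroups
        prof = gd.diagnostic_positions("AAGGCCTT", ["AAGACCTT", "AAGTCCTT"], aligned=True)
        assert prof.positions == (3,)

    def test_gap_in_any_outgroup_disqualifies(self):
        prof = gd.diagnostic_positions("ACGT", ["AC-T", "ACAT"], aligned=True)
        assert prof.positions == ()

    def test_positions_reported_on_ungapped_target(self):
        prof = gd.diagnostic_positions("AC-GT", ["ACAGA"], aligned=True)
        assert prof.positions == (3,)  # ungapped target is ACGT

    def test_zero_outgroups_is_an_error(self):
        with pytest.raises(ValueError):
            gd.diagnostic_positions("ACGT", [])

    def test_unaligned_inputs_go_through_the_aligner(self):
        target = "ACGTACGTACGTACGTACGT"
        outgroup = target[:9] + target[10:]  # one deletion, no substitutions
        prof = gd.diagnostic_positions(target, [outgroup], aligned=False)
        assert prof.positions == ()  # gap columns are disqualified


class TestEnumerate:
    def test_direct_construction(self):
        seq = "A" * 5 + "T" + "A" * 15 + "GG"
        prof = gd.DiagnosticProfile("t", ("o",), (5,))
        (cand,) = gd.enumerate_guide_candidates(seq, prof)
        assert cand.pam_side == "three_prime_NGG"
        assert cand.diagnostic_hits == (5,)
        assert not cand.diag_in_pam_GGCC

    def test_no_pam_no_candidates(self):
        seq = "ATATATATATATATATATATATA"
        prof = gd.DiagnosticProfile("t", ("o",), (5,))
        assert gd.enumerate_guide_candidates(seq, prof) == []

    def test_window_shorter_than_k(self):
        prof = gd.DiagnosticProfile("t", ("o",), (5,))
        assert gd.enumerate_guide_candidates("A" * 22, prof) == []

    def test_every_candidate_has_diag_and_pam(self, toy_lib):
        target = toy_lib["L1Hs"]
        prof = gd.diagnostic_positions(target, [toy_lib["L1PA2"]], aligned=True)
        cands = gd.enumerate_guide_candidates(target, prof)
        assert cands
        for c in cands:
            assert c.diagnostic_hits
            if c.pam_side == "three_prime_NGG":
                assert c.seq23[21:23] == "GG"
            else:
                assert c.seq23[:2] == "CC"
            assert target.seq[c.consensus_pos : c.consensus_pos + 23] == c.seq23


class TestKmerCounting:
    def test_overlapping_both_strand_count(self):
        # sliding-window oracle: AA occurs 3x forward; its complement TT
        # never occurs on the reverse strand of an all-A genome
        g = SequenceRecord("g", "AAAA")
        assert gd.count_kmer_frequency([g], ["AA"])["AA"] == 3
        # a palindromic k-mer is counted once per strand
        g2 = SequenceRecord("g", "ATAT")
        assert gd.count_kmer_frequency([g2], ["AT"])["AT"] == 4  # 2 forward + 2 reverse

    def test_absent_kmer(self):
        g = SequenceRecord("g", "CCCCCC")
        assert gd.count_kmer_frequency([g], ["GA"], both_strands=False)["GA"] == 0

    def test_reverse_complement_hit(self):
        g = SequenceRecord("g", "AAAT")
        assert gd.count_kmer_frequency([g], ["ATTT"])["ATTT"] == 1

    def test_kmer_with_n_rejected(self):
        with pytest.raises(ValueError):
            gd.count_kmer_frequency([SequenceRecord("g", "ACGT")], ["AN"])

    def test_pam_substitution_expands_n_position(self):
        # genome holds CCA once and CCG once; querying CCA with the N at
        # index 2 expanded must count both
        g = SequenceRecord("g", "CCATTCCGTT")
        n = gd.count_kmer_frequency([g], ["CCA"], pam_substitution=True, n_index=2,
                                    both_strands=False)["CCA"]
        assert n == 2

    def test_matches_naive_sliding_window(self):
        rng = np.random.default_rng(3)
        text = _rand(rng, 20_000)
        g = SequenceRecord("g", text)
        kmers = ["".join(k) for k in (_rand(rng, 6) for _ in range(20))]
        counts = gd.count_kmer_frequency([g], kmers)
        for k in kmers:
            naive = sum(text[i : i + 6] == k for i in range(len(text) - 5))
            naive += sum(text[i : i + 6] == revcomp(k) for i in range(len(text) - 5))
            assert counts[k] == naive


class TestTiersAndRanking:
    def _cand(self, diag_pam=False, freq=0, pos=0):
        c = gd.GuideCandidate("A" * 21 + "GG", "three_prime_NGG", pos, (5,), diag_pam)
        c.genome_freq = freq
        return c

    def test_tier0_on_pam_diagnostic(self):
        assert gd.assign_tier(self._cand(diag_pam=True, freq=10**6), 100) == "Tier0"

    def test_tier1_frequency_in_range(self):
        assert gd.assign_tier(self._cand(freq=150), 100) == "Tier1"

    def test_tier2_frequency_out_of_range(self):
        assert gd.assign_tier(self._cand(freq=300), 100) == "Tier2"

    def test_bad_copy_count(self):
        with pytest.raises(ValueError):
            gd.assign_tier(self._cand(freq=1), 0)

    def test_tier0_ranks_first(self):
        a, b = self._cand(freq=300, pos=0), self._cand(diag_pam=True, freq=300, pos=50)
        gd.assign_tier(a, 100), gd.assign_tier(b, 100)
        assert gd.rank_guides([a, b], consensus_len=200)[0] is b

    def test_three_prime_proximity_breaks_ties(self):
        a, b = self._cand(freq=10, pos=0), self._cand(freq=10, pos=100)
        gd.assign_tier(a, 100), gd.assign_tier(b, 100)
        assert gd.rank_guides([a, b], consensus_len=200)[0] is b

    def test_single_candidate(self):
        a = self._cand(freq=10)
        gd.assign_tier(a, 100)
        assert gd.rank_guides([a], consensus_len=100) == [a]


class TestBoundClassification:
    GUIDE = "ACGTTGCAACGTTGCAACGTAGG"

    def test_exact_match_is_lower(self):
        el = "TTTT" + self.GUIDE + "CCCC"
        assert gd.classify_guide_match(self.GUIDE, el) == "lower"

    def test_two_substitutions_is_intermediate(self):
        mutated = list(self.GUIDE)
        mutated[5] = "A" if self.GUIDE[5] != "A" else "C"
        mutated[15] = "T" if self.GUIDE[15] != "T" else "G"
        el = "AAAA" + "".join(mutated) + "GGGA"
        assert gd.classify_guide_match(self.GUIDE, el) == "intermediate"

    def test_reverse_strand_exact_match_counts(self):
        el = "TTTT" + revcomp(self.GUIDE) + "CCCC"
        assert gd.classify_guide_match(self.GUIDE, el) == "lower"

    def test_weak_match_is_none(self):
        # a 16 bp poly-G element can match at most the guide's 7 G bases
        el = "G" * 16
        from tests.test_align import oracle_semiglobal

        best = max(
            oracle_semiglobal(self.GUIDE, el)[1], oracle_semiglobal(self.GUIDE, revcomp(el))[1]
        )
        assert best < 14
        assert gd.classify_guide_match(self.GUIDE, el) == "none"

    def test_short_element_is_none(self):
        assert gd.classify_guide_match(self.GUIDE, "ACGT") == "none"

    def test_nesting_on_simulated_copies(self):
        rng = np.random.default_rng(21)
        n = {"lower": 0, "intermediate": 0, "upper": 0}
        for i in range(40):
            el = list(_rand(rng, 30) + self.GUIDE + _rand(rng, 30))
            for _ in range(i % 6):  # 0..5 point edits at the guide site
                j = 30 + int(rng.integers(0, 23))
                el[j] = "ACGT"[int(rng.integers(0, 4))]
            cls = gd.classify_guide_match(self.GUIDE, "".join(el))
            if cls != "none":
                for b in gd.BOUND_ORDER[gd.BOUND_ORDER.index(cls) :]:
                    n[b] += 1
        assert n["lower"] <= n["intermediate"] <= n["upper"]
        assert n["lower"] > 0 and n["upper"] > n["lower"]


class TestCaptureBounds:
    def test_counts_match_per_copy_classification(self):
        rng = np.random.default_rng(5)
        guide = toy_guide("L1Hs")
        chunks, feats, expected = [], [], []
        pos = 0
        for i in range(12):
            el = list(_rand(rng, 20) + guide + _rand(rng, 20))
            for _ in range(i % 5):
                j = 20 + int(rng.integers(0, 23))
                el[j] = "ACGT"[int(rng.integers(0, 4))]
            el = "".join(el)
            expected.append(gd.classify_guide_match(guide, el))
            chunks.append(el)
            feats.append(RepeatFeature("g", pos, pos + len(el), "+", "L1", "L1Hs"))
            pos += len(el)
        genome = SequenceRecord("g", "".join(chunks))
        summary = gd.compute_capture_bounds(guide, genome, feats)
        row = summary.get("L1Hs", "reference")
        for bound in gd.BOUND_ORDER:
            want = sum(
                1 for e in expected if e != "none" and gd.BOUND_ORDER.index(e) <= gd.BOUND_ORDER.index(bound)
            )
            assert row[bound] == want
        assert row["lower"] <= row["intermediate"] <= row["upper"]

    def test_all_exact_copies(self):
        guide = toy_guide("AluYb8")
        el = "AAAA" + guide + "TTTT"
        genome = SequenceRecord("g", el * 5)
        feats = [RepeatFeature("g", i * len(el), (i + 1) * len(el), "+", "Alu", "AluYb8") for i in range(5)]
        row = gd.compute_capture_bounds(guide, genome, feats).get("AluYb8", "reference")
        assert row == {"lower": 5, "intermediate": 5, "upper": 5}

    def test_empty_element_set(self):
        genome = SequenceRecord("g", "ACGT" * 10)
        summary = gd.compute_capture_bounds(toy_guide("L1Hs"), genome, [])
        assert summary.counts == {}

    def test_feature_outside_genome_is_an_error(self):
        genome = SequenceRecord("g", "ACGT" * 10)
        feats = [RepeatFeature("g", 0, 100, "+", "L1", "L1Hs")]
        with pytest.raises(ValueError):
            gd.compute_capture_bounds(toy_guide("L1Hs"), genome, feats)


class TestToyDesignIntegration:
    def test_toy_l1hs_yields_tier0_guide_near_three_prime(self, toy_lib):
        target = toy_lib["L1Hs"]
        rng = np.random.default_rng(2)
        genome = SequenceRecord("g", _rand(rng, 30_000) + target.seq + _rand(rng, 5_000))
        ranked = gd.design_guides(target, [toy_lib["L1PA2"]], genome, target_copy_count=1, aligned=True)
        top = ranked[0]
        assert top.tier == "Tier0"
        # the winner sits in the engineered 3'-end site region
        g = TOY_GUIDE_SITES["L1Hs"]
        assert g - 23 < top.consensus_pos < g + 23
        # the engineered NGG window itself is a Tier0 candidate
        engineered = [c for c in ranked if c.consensus_pos == g and c.pam_side == "three_prime_NGG"]
        assert engineered and engineered[0].tier == "Tier0"
        assert engineered[0].seq23 == toy_guide("L1Hs")

    def test_engineered_diagnostics_detected_for_every_toy_target(self, toy_lib):
        outgroups = {
            "L1Hs": ["L1PA2"],
            "AluYb8": ["AluY", "AluYa5"],
            "AluYa5": ["AluY", "AluYb8"],
            "SVA_F": ["SVA_D", "SVA_E"],
            "SVA_E": ["SVA_D", "SVA_F"],
        }
        for sub, outs in outgroups.items():
            prof = gd.diagnostic_positions(toy_lib[sub], [toy_lib[o] for o in outs], aligned=False)
            g = TOY_GUIDE_SITES[sub]
            in_window = [p for p in prof.positions if g <= p < g + 23]
            assert len(in_window) >= 3, sub
            assert g + 21 in in_window, sub  # the PAM-G diagnostic
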