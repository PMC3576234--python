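"""Hairpin validation, miRNA locus calling, and reference comparison."""

import pytest

from oracles import naive_revcomp
from srnakit.align import AlignmentHit
from srnakit.config import PipelineConfig
from srnakit.fold import FoldResult, fold, pairs_to_dotbracket, parse_stemloops
from srnakit.hairpin import (
    call_mirna_loci, classify_locus, compare_to_reference, extract_window,
    validate_hairpin,
)
from srnakit.io import FeatureInterval, SequenceRecord, revcomp


def _hit(start, end, strand="+", rid="r", contig="c1"):
    return AlignmentHit(read_id=rid, contig=contig, start=start, end=end,
                        strand=strand, mismatches=0)


def _chain_fold(L, arm5, arm3):
    """FoldResult whose pairs chain arm5 positions to arm3 positions."""
    assert len(arm5) == len(arm3)
    pairs = tuple(sorted(zip(sorted(arm5), sorted(arm3, reverse=True))))
    return FoldResult(window_seq="A" * L,
                      dotbracket=pairs_to_dotbracket(L, pairs),
                      pairs=pairs, score=len(pairs))


def _spread(start, end, n):
    """n integer positions spanning [start, end] inclusive, endpoints kept."""
    assert n >= 2
    step = (end - start) / (n - 1)
    positions = sorted({start + round(i * step) for i in range(n)})
    assert len(positions) == n and positions[0] == start and positions[-1] == end
    return positions


class TestExtractWindow:
    def test_plus_strand_arithmetic(self):
        genome = {"c1": "A" * 1000}
        seq, off, trunc = extract_window(_hit(100, 122), genome, flank=50)
        assert len(seq) == 122 and off == (50, 72) and not trunc

    def test_edge_clamp_sets_truncated(self):
        genome = {"c1": "A" * 1000}
        seq, off, trunc = extract_window(_hit(10, 32), genome, flank=50)
        assert len(seq) == 82 and off == (10, 32) and trunc

    def test_minus_strand_window_is_revcomp_with_mirrored_offsets(self):
        contig = "ACGTGGTTCCAATTGGCCAAGGTTACGTACGTTGCA" * 4
        genome = {"c1": contig}
        plus, off_p, _ = extract_window(_hit(60, 80, "+"), genome, flank=20)
        minus, off_m, _ = extract_window(_hit(60, 80, "-"), genome, flank=20)
        assert minus == naive_revcomp(plus)
        assert off_m == (len(plus) - off_p[1], len(plus) - off_p[0])


class TestVerdictTruthTable:
    """All eight verdict combinations from constructed stem-loop geometries.

    Fractions bracket the 75% stem-pairing rule at 0.74 and 0.76; the read
    is placed on an arm, in the terminal loop, or straddling the stem edge.
    """

    L = 140

    def _frac10_loop(self):  # 30 stacked pairs, frac 1.0, loop 80..99
        return _chain_fold(self.L, list(range(50, 80)), list(range(100, 130)))

    def _frac074_loop(self):  # 37 pairs over 50+50 arm bases, loop 80..89
        return _chain_fold(self.L, _spread(30, 79, 37), _spread(90, 139, 37))

    def _frac076_loop(self):  # 19 pairs over 25+25 arm bases
        return _chain_fold(self.L, _spread(55, 79, 19), _spread(90, 114, 19))

    def _frac10_noloop(self):  # adjacent innermost pair: loop length 0
        return _chain_fold(self.L, list(range(50, 90)), list(range(90, 130)))

    def _frac074_noloop(self):
        return _chain_fold(self.L, _spread(30, 79, 37), _spread(80, 129, 37))

    @pytest.mark.parametrize("fold_r,read,expected", [
        # (has_loop, stem_frac_ok, read_in_stem)
        ("_frac10_loop", (60, 80), (True, True, True)),
        ("_frac10_loop", (85, 95), (True, True, False)),     # read in loop
        ("_frac074_loop", (60, 80), (True, False, True)),
        ("_frac074_loop", (82, 88), (True, False, False)),
        ("_frac10_noloop", (60, 80), (False, True, True)),
        ("_frac10_noloop", (40, 60), (False, True, False)),  # straddles edge
        ("_frac074_noloop", (60, 80), (False, False, True)),
        ("_frac074_noloop", (20, 40), (False, False, False)),
    ], ids=["pass", "read_in_loop", "sparse_stem", "sparse_stem_loop_read",
            "no_loop", "no_loop_edge_read", "sparse_no_loop", "all_fail"])
    def test_verdict_combinations(self, cfg, fold_r, read, expected):
        fr = getattr(self, fold_r)()
        call = validate_hairpin(_hit(0, 1), fr, read, (0, self.L), False, cfg)
        assert (call.has_loop, call.stem_frac_ok, call.read_in_stem) == expected
        assert call.passed == all(expected)

    def test_borderline_076_passes(self, cfg):
        call = validate_hairpin(_hit(0, 1), self._frac076_loop(), (60, 80),
                                (0, self.L), False, cfg)
        assert call.stem_frac_ok and call.passed

    def test_no_overlapping_stemloop_fails_all(self, cfg):
        call = validate_hairpin(_hit(0, 1), self._frac10_loop(), (0, 20),
                                (0, self.L), False, cfg)
        assert call.stemloop is None and not call.passed

    def test_loop_overhang_tolerance(self):
        tolerant = PipelineConfig(loop_overhang=2)
        fr = self._frac10_loop()
        call = validate_hairpin(_hit(0, 1), fr, (62, 82), (0, self.L), False,
                                tolerant)
        assert call.read_in_stem  # 2 loop bases tolerated
        strict = PipelineConfig(loop_overhang=0)
        call2 = validate_hairpin(_hit(0, 1), fr, (62, 82), (0, self.L), False,
                                 strict)
        assert not call2.read_in_stem

    def test_monotone_in_stem_fraction_threshold(self):
        fr = self._frac076_loop()
        passed = []
        for threshold in (0.5, 0.7, 0.76, 0.9, 1.0):
            cfg = PipelineConfig(min_stem_paired_frac=threshold)
            call = validate_hairpin(_hit(0, 1), fr, (60, 80), (0, self.L),
                                    False, cfg)
            passed.append(call.stem_frac_ok)
        assert passed == sorted(passed, reverse=True)  # raising never re-passes


class TestCallLoci:
    def _planted_genome(self, cfg):
        arm = "GCTAGTCGATCGGATCAGTCCTACG"  # 25 nt
        hairpin = arm + "TTTGTT" + revcomp(arm)
        left = "ATGTACCTGATACGTGCATGGCTAAGCTATCAGGCATCACAATGTAGCAC"
        right = "TGCATCACGGTTAGCATGACCATGGATCATACCAGGCATTACAGTACCAG"
        return {"c1": left + hairpin + right}, len(left), arm

    def test_read_on_planted_arm_is_bona_fide(self, cfg):
        genome, start, arm = self._planted_genome(cfg)
        hit = _hit(start + 2, start + 22, rid="m1")
        bona, loci, calls = call_mirna_loci({"m1": [hit]}, genome, cfg)
        assert bona == {"m1"} and len(loci) == 1

    def test_one_passing_hit_suffices(self, cfg):
        genome, start, arm = self._planted_genome(cfg)
        good = _hit(start + 2, start + 22, rid="m1")
        bad = _hit(5, 25, rid="m1")  # unstructured flank
        bona, loci, calls = call_mirna_loci({"m1": [bad, good]}, genome, cfg)
        assert "m1" in bona

    def test_overlapping_windows_merge_into_one_locus(self, cfg):
        genome, start, arm = self._planted_genome(cfg)
        h1 = _hit(start + 1, start + 21, rid="m1")
        h2 = _hit(start + 4, start + 24, rid="m2")
        bona, loci, _ = call_mirna_loci({"m1": [h1], "m2": [h2]}, genome, cfg)
        assert len(loci) == 1
        assert loci[0].read_ids == {"m1", "m2"} and loci[0].n_reads == 2

    def test_read_in_unstructured_sequence_not_called(self, cfg):
        genome = {"c1": "ATGTACCTGATACGTGCATGACTAAGCTATCAGGCATCACAATGTAGCAC" * 3}
        bona, loci, _ = call_mirna_loci({"m1": [_hit(60, 80, rid="m1")]},
                                        genome, cfg)
        # this particular window folds without a qualifying read-bearing stem
        assert bona == set() and loci == []


class TestReferenceComparison:
    REF_HAIRPIN = ("GCGGCCTTAGCTCAGTTGGTAGAGCA" "TTTGTT"
                   "TGCTCTACCAACTGAGCTAAGGCCGC")

    def _reference(self):
        mature = self.REF_HAIRPIN[2:24]
        return [(SequenceRecord(id="ref-mir-1", seq=self.REF_HAIRPIN),
                 SequenceRecord(id="ref-mir-1", seq=mature))]

    def test_identical_candidate_scores_identity_one(self, cfg):
        mature = self.REF_HAIRPIN[2:24]
        best = compare_to_reference(self.REF_HAIRPIN, mature, self._reference(), cfg)
        assert best is not None and best.identity == 1.0

    def test_one_substitution_still_accepted(self, cfg):
        mature = list(self.REF_HAIRPIN[2:24])
        mature[10] = "A" if mature[10] != "A" else "C"
        best = compare_to_reference(self.REF_HAIRPIN, "".join(mature),
                                    self._reference(), cfg)
        assert best is not None
        assert best.identity == pytest.approx(21 / 22)
        assert best.identity >= cfg.ref_min_identity

    def test_two_substitutions_rejected(self, cfg):
        mature = list(self.REF_HAIRPIN[2:24])
        for pos in (5, 10):
            mature[pos] = "A" if mature[pos] != "A" else "C"
        assert 20 / 22 < cfg.ref_min_identity
        assert compare_to_reference(self.REF_HAIRPIN, "".join(mature),
                                    self._reference(), cfg) is None

    def test_invariant_under_candidate_revcomp(self, cfg):
        mature = self.REF_HAIRPIN[2:24]
        fwd = compare_to_reference(self.REF_HAIRPIN, mature, self._reference(), cfg)
        rev = compare_to_reference(revcomp(self.REF_HAIRPIN), mature,
                                   self._reference(), cfg)
        assert fwd is not None and rev is not None
        assert fwd.ref_id == rev.ref_id and fwd.identity == rev.identity

    def test_no_shared_seed_means_no_hit(self, cfg):
        candidate = "ATATATATATATATATATATATATATATATAT"
        best = compare_to_reference(candidate, candidate[:22], self._reference(), cfg)
        assert best is None


class TestClassifyLocus:
    def _locus(self):
        from srnakit.hairpin import MirnaLocus

        return MirnaLocus(contig="c1", start=100, end=220, strand="+")

    def _gene(self, start, end, biotype):
        return FeatureInterval("c1", start, end, "+", "gene", biotype, biotype)

    def test_known_mirna_gene_wins_precedence(self):
        anns = [self._gene(150, 400, "miRNA"), self._gene(50, 500, "protein_coding")]
        assert classify_locus(self._locus(), anns) == "known_mirna_gene"

    def test_protein_coding_overlap(self):
        assert classify_locus(self._locus(),
                              [self._gene(0, 150, "protein_coding")]) \
            == "protein_coding_overlap"

    def test_pseudogene_overlap(self):
        assert classify_locus(self._locus(), [self._gene(210, 400, "pseudogene")]) \
            == "pseudogene_overlap"

    def test_intergenic_when_nothing_overlaps(self):
        assert classify_locus(self._locus(), [self._gene(500, 900, "miRNA")]) \
            == "intergenic"
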