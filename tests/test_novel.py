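from __future__ import annotations

import pytest

from mirvar import fixtures as fx
from mirvar.formats import MatureRecord, revcomp
from mirvar.novel import (
    GenomeStack,
    NovelMature,
    NovelPrecursor,
    build_signature,
    build_stacks,
    excise_candidates,
    map_perfect,
    predict_library,
    score_candidates,
    seed_match,
    select_mature,
    unify_names,
)
from mirvar.preprocess import CollapsedRead


def _cread(uid, seq, count):
    return CollapsedRead(uid, seq, count)


@pytest.fixture(scope="module")
def planted():
    """A genome with an embedded (unannounced) hairpin and supporting reads."""
    hairpin, _, _ = fx.make_hairpin(seed=23, index=77, bulges=4)
    fixture = fx.make_genome([hairpin], seed=23)
    reads, mature = fx.make_novel_reads(fixture, hairpin)
    return fixture, hairpin, reads, mature


class TestMapPerfect:
    def test_length_window_and_loci_cap(self, planted):
        fixture, _, _, mature = planted
        genome = fixture.genome
        long_read = _cread("1-1", genome["chr1"][10:36], 1)   # 26 nt: too long
        short_read = _cread("2-1", genome["chr1"][10:27], 1)  # 17 nt: too short
        good = _cread("3-1", mature, 1)
        hits = map_perfect([long_read, short_read, good], genome)
        assert {h.read_uid for h in hits} == {"3-1"}

    def test_multi_locus_reads_excluded(self):
        unit = "ACGTACGTACGTACGTACGTAC"  # 22 nt repeated 6 times
        genome = {"chr1": ("A" * 50) + unit * 6 + ("T" * 50)}
        read = _cread("1-1", unit, 4)
        assert map_perfect([read], genome) == []

    def test_minus_strand_mapping(self, planted):
        fixture, _, _, mature = planted
        read = _cread("1-2", revcomp(mature), 2)
        hits = map_perfect([read], fixture.genome)
        assert hits and all(h.strand == "-" for h in hits)


class TestBuildStacks:
    def test_overlapping_mappings_merge(self, planted):
        fixture, hairpin, reads, mature = planted
        from mirvar.preprocess import collapse

        collapsed = collapse(reads)
        stacks = build_stacks(map_perfect(collapsed, fixture.genome))
        assert len(stacks) == 1
        assert stacks[0].count == 35  # 30 + 5 overlapping

    def test_disjoint_mappings_stay_separate(self):
        genome = {"chr1": "A" * 20 + "ACGTTGCATGCTAGCTAGGTCC" + "T" * 50
                  + "GGCATCGATTACGCTAGCTAAC" + "A" * 20}
        r1 = _cread("1-5", genome["chr1"][20:42], 5)
        r2 = _cread("2-3", genome["chr1"][92:114], 3)
        stacks = build_stacks(map_perfect([r1, r2], genome))
        assert len(stacks) == 2
        assert [s.count for s in stacks] == [5, 3]


class TestExcise:
    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 300}
        stack = GenomeStack("chr1", "+", 100, 122, ("1-1",), 1)
        cands = excise_candidates(genome, stack)
        assert [(c.start, c.end) for c in cands] == [(90, 192), (30, 132)]

    def test_chromosome_start_clipping(self):
        genome = {"chr1": "A" * 300}
        stack = GenomeStack("chr1", "+", 5, 27, ("1-1",), 1)
        cands = excise_candidates(genome, stack)
        assert cands[0].start == 0

    def test_minus_strand_reverse_complemented(self):
        seq = "".join("ACGT"[i % 4] for i in range(300))
        genome = {"chr1": seq}
        stack = GenomeStack("chr1", "-", 100, 122, ("1-1",), 1)
        cands = excise_candidates(genome, stack)
        assert cands[0].sequence == revcomp(seq[90:192])


class TestSignature:
    CAND = NovelPrecursor("", "chr1", "+", 0, 0, "G" * 5 + "TGAGGTAGTAGGTTGTATAGTT" + "C" * 40)

    def test_perfect_only(self):
        mature = self.CAND.sequence[5:27]
        mutated = "A" + mature[1:]
        hits = build_signature([_cread("1-5", mature, 5), _cread("2-3", mutated, 3)], [], self.CAND)
        assert {h.read_uid for h in hits} == {"1-5"}

    def test_length_window(self):
        hits = build_signature([_cread("1-5", self.CAND.sequence[5:22], 5)], [], self.CAND)
        assert hits == []  # 17 nt below the signature window

    def test_known_mature_flagged(self):
        known = MatureRecord("xxx-miR-9-5p", self.CAND.sequence[5:27])
        hits = build_signature([], [known], self.CAND)
        assert hits and hits[0].is_known_mature


class TestSelectMature:
    CAND = NovelPrecursor("", "chr1", "+", 0, 0, "N" * 100)

    def _hit(self, uid, count, start, seq="A" * 22):
        from mirvar.novel import SignatureHit

        return SignatureHit(uid, count, seq, start, start + len(seq))

    def test_dominant_stack_selected(self):
        sig = [self._hit("1-30", 30, 10, "A" * 22), self._hit("2-10", 10, 40, "C" * 22)]
        assert select_mature(self.CAND, sig) == "A" * 22

    def test_twofold_exactly_discarded(self):
        sig = [self._hit("1-20", 20, 10), self._hit("2-10", 10, 40, "C" * 22)]
        assert select_mature(self.CAND, sig) is None

    def test_single_stack_accepted(self):
        sig = [self._hit("1-7", 7, 10)]
        assert select_mature(self.CAND, sig) == "A" * 22

    def test_known_matures_do_not_count(self):
        from mirvar.novel import SignatureHit

        sig = [
            self._hit("1-10", 10, 10),
            SignatureHit("known", 0, "C" * 22, 40, 62, is_known_mature=True),
        ]
        assert select_mature(self.CAND, sig) == "A" * 22


class TestScoreCandidates:
    CAND = NovelPrecursor(
        "", "chr1", "+", 0, 122, "A" * 30, mature=NovelMature("", "A" * 10)
    )

    def test_negative_score_dropped(self):
        assert score_candidates([self.CAND], lambda seq: (None, -1.0)) == []

    def test_no_backend_passes_through_unscored(self):
        (out,) = score_candidates([self.CAND], None)
        assert out.status == "unscored"

    def test_structure_recorded_with_positive_score(self):
        structure = "." * 30
        (out,) = score_candidates([self.CAND], lambda seq: (structure, 3.0))
        assert out.status == "scored"
        assert out.dot_bracket == structure
        assert out.score == 3.0

    def test_self_paired_mature_dropped(self):
        # mature occupies [0,10); structure pairs base 2 with base 7
        structure = "..(....).." + "." * 20
        assert score_candidates([self.CAND], lambda seq: (structure, 3.0)) == []


class TestUnifyNames:
    def _cand(self, start, mature_seq, lib_seq="A" * 100):
        return NovelPrecursor(
            "", "chr1", "+", start, start + 100, lib_seq,
            mature=NovelMature("", mature_seq),
        )

    def test_same_coordinates_one_precursor(self):
        c = self._cand(100, "A" * 22)
        precs, matures, observed = unify_names({"lib1": [c], "lib2": [c]}, "syn")
        assert len(precs) == 1
        assert precs[0].name == "syn-novel-mir-1"
        assert list(matures) == ["syn-novel-miR-1"]
        assert observed["syn-novel-miR-1"] == {"lib1", "lib2"}

    def test_numbering_by_genomic_order_and_input_invariance(self):
        c1, c2 = self._cand(500, "A" * 22), self._cand(100, "C" * 22)
        precs_a, _, _ = unify_names({"lib1": [c1, c2]}, "syn")
        precs_b, _, _ = unify_names({"lib1": [c2, c1]}, "syn")
        assert [p.name for p in precs_a] == [p.name for p in precs_b]
        assert precs_a[0].start == 100  # lowest coordinate gets number 1

    def test_distinct_matures_get_suffixes(self):
        a = self._cand(100, "A" * 22)
        b = self._cand(100, "C" * 22)
        _, matures, _ = unify_names({"lib1": [a], "lib2": [b]}, "syn")
        assert sorted(matures) == ["syn-novel-miR-1a", "syn-novel-miR-1b"]

    def test_seed_match_annotation(self):
        known = [MatureRecord("xxx-miR-1-3p", "TGAGGTAGTAGGTTGTATAGTT")]
        assert seed_match("AGAGGTAGTAGGTTGTATAGTT"[:22], known) == "xxx-miR-1-3p"
        assert seed_match("ACCCCCCCCCCCCCCCCCCCCC", known) is None


class TestPlantedRecovery:
    def test_planted_hairpin_recovered_end_to_end(self, planted):
        """Stack -> excision -> signature -> mature selection recovers exactly
        the planted hairpin's dominant-arm mature."""
        from mirvar.preprocess import collapse

        fixture, hairpin, reads, mature = planted
        collapsed = collapse(reads)
        candidates = predict_library(collapsed, fixture.genome)
        assert len(candidates) == 1
        cand = candidates[0]
        assert cand.mature is not None
        assert cand.mature.sequence == mature
        chrom, start, end = fixture.hairpin_spans[hairpin.hairpin_id]
        assert cand.start <= start and cand.end >= start + 22
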