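from __future__ import annotations

from fractions import Fraction

import pytest

from mirvar.fixtures import make_hairpin
from mirvar.formats import HairpinRecord
from mirvar.hairpin_align import HairpinAlignment, MatureLocus, align_read, map_all
from mirvar.preprocess import CollapsedRead
from mirvar.quantify import (
    QuantSettings,
    QuantTable,
    assign_counts,
    family_counts,
    position_check,
    round_half_away,
    round_table,
    seed_check,
)


def _aln(hairpin_id="h", start=10, end=32, ops=(("=", 22),), penalty=0,
         clip5=0, clip3=0, nmm=0, nins=0, ndel=0, uid="1-1"):
    return HairpinAlignment(
        read_uid=uid, hairpin_id=hairpin_id, start=start, end=end, ops=ops,
        penalty=penalty, n_mismatch=nmm, n_ins_bases=nins, n_del_bases=ndel,
        clip5_len=clip5, clip3_len=clip3,
    )


LOCUS = MatureLocus("m-5p", "h", 10, 32, "5p")


class TestPositionCheck:
    @pytest.mark.parametrize(
        "start, end, passes",
        [
            (10, 32, True),   # exact
            (7, 32, True),    # 3 nt upstream: boundary inclusive
            (6, 32, False),   # 4 nt upstream
            (10, 36, False),  # 3' end 4 nt beyond
            (13, 29, True),   # both ends shifted 3
        ],
    )
    def test_shift_boundaries(self, start, end, passes):
        hit = position_check(_aln(start=start, end=end), [LOCUS])
        assert (hit is not None) is passes

    def test_minimal_total_shift_wins_tie_to_5p(self):
        loci = [
            MatureLocus("m-3p", "h", 12, 34, "3p"),
            MatureLocus("m-5p", "h", 10, 32, "5p"),
            MatureLocus("far-5p", "h", 40, 62, "5p"),
        ]
        locus, s5, s3 = position_check(_aln(start=11, end=33), loci)
        assert locus.mature_id in {"m-5p", "m-3p"}
        # both are 2 total shifts away; tie goes to the 5p arm
        assert locus.mature_id == "m-5p"
        assert (s5, s3) == (1, 1)


HAIRPIN = "G" * 10 + "TGAGGTAGTAGGTTGTATAGTT" + "C" * 10  # mature at [10, 32)


class TestSeedCheck:
    def test_canonical_read_passes(self):
        assert seed_check(HAIRPIN[10:32], _aln(), LOCUS, HAIRPIN)

    def test_upstream_start_fails(self):
        aln = _aln(start=9, end=32, ops=(("=", 23),))
        assert not seed_check(HAIRPIN[9:32], aln, LOCUS, HAIRPIN)

    def test_five_prime_clip_fails(self):
        aln = _aln(clip5=2, ops=(("S", 2), ("=", 20)), start=10, end=30)
        assert not seed_check("GG" + HAIRPIN[10:30], aln, LOCUS, HAIRPIN)

    @pytest.mark.parametrize("mm_pos, passes", [(5, False), (12, True)])
    def test_mismatch_inside_vs_outside_window(self, mm_pos, passes):
        # read position mm_pos (1-based); seed window is 2-8
        ops = (("=", mm_pos - 1), ("X", 1), ("=", 22 - mm_pos))
        read = list(HAIRPIN[10:32])
        read[mm_pos - 1] = "A" if read[mm_pos - 1] != "A" else "G"
        aln = _aln(ops=ops, penalty=30, nmm=1)
        assert seed_check("".join(read), aln, LOCUS, HAIRPIN) is passes

    def test_deletion_before_window_end_fails(self):
        ops = (("=", 4), ("D", 1), ("=", 17))
        aln = _aln(ops=ops, end=32, penalty=46, ndel=1)
        assert not seed_check(HAIRPIN[10:14] + HAIRPIN[15:32], aln, LOCUS, HAIRPIN)


def _quantify_planted(hairpins, reads, loci, settings=QuantSettings()):
    mappings, _ = map_all(reads, hairpins)
    hairpin_seqs = {h.hairpin_id: h.sequence for h in hairpins}
    return assign_counts(reads, mappings, loci, hairpin_seqs, settings)


class TestAssignCounts:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        hp, m5, m3 = make_hairpin(seed=17, index=1)
        loci = [
            MatureLocus(m5.mature_id, hp.hairpin_id, 0, 22, "5p"),
            MatureLocus(m3.mature_id, hp.hairpin_id, 34, 56, "3p"),
        ]
        return hp, m5, loci

    def test_unique_mapping_full_count(self, planted):
        hp, m5, loci = planted
        reads = [CollapsedRead("1-10", m5.sequence, 10)]
        quant = _quantify_planted([hp], reads, loci)
        assert quant.counts[m5.mature_id] == 10

    def test_duplicated_hairpin_splits_evenly(self, planted):
        hp, m5, loci = planted
        twin = HairpinRecord("syn-mir-9", hp.sequence)
        loci2 = loci + [MatureLocus("syn-miR-9-5p", "syn-mir-9", 0, 22, "5p")]
        reads = [CollapsedRead("1-10", m5.sequence, 10)]
        quant = _quantify_planted([hp, twin], reads, loci2)
        assert quant.counts[m5.mature_id] == 5
        assert quant.counts["syn-miR-9-5p"] == 5

    def test_three_way_split_keeps_exact_thirds(self, planted):
        hp, m5, loci = planted
        twins = [HairpinRecord(f"syn-mir-{i}", hp.sequence) for i in (7, 8)]
        loci2 = loci + [
            MatureLocus(f"syn-miR-{i}-5p", f"syn-mir-{i}", 0, 22, "5p") for i in (7, 8)
        ]
        reads = [CollapsedRead("1-9", m5.sequence, 9)]
        quant = _quantify_planted([hp] + twins, reads, loci2)
        assert quant.counts[m5.mature_id] == Fraction(9, 3)
        assert quant.total() == 9

    def test_clip_free_mapping_takes_priority(self):
        # two qualified mappings, clip totals {0, 2}: all count to the clip-free one
        loci = [LOCUS, MatureLocus("m2-5p", "h2", 10, 32, "5p")]
        alns = [
            _aln(hairpin_id="h", uid="1-10"),
            _aln(hairpin_id="h2", uid="1-10", clip3=2,
                 ops=(("=", 20), ("S", 2)), start=10, end=30),
        ]
        reads = [CollapsedRead("1-10", HAIRPIN[10:32], 10)]
        quant = assign_counts(
            reads, {"1-10": alns}, loci, {"h": HAIRPIN, "h2": HAIRPIN},
            QuantSettings(seed_check=False),
        )
        assert quant.counts["m-5p"] == 10
        assert quant.counts["m2-5p"] == 0

    def test_conservation_on_mixed_library(self, quantified):
        collapsed, mappings, quant, manifest = quantified
        assert quant.total() == quant.tallies["counted"]
        assert quant.tallies["counted"] == sum(manifest.expected_counts_per_mature.values())

    def test_seed_check_never_increases_counts(self, reference, mixed_library):
        from mirvar.preprocess import collapse

        hairpins, _, loci = reference
        reads, _ = mixed_library
        collapsed = collapse(reads)
        on = _quantify_planted(hairpins, collapsed, loci, QuantSettings(seed_check=True))
        off = _quantify_planted(hairpins, collapsed, loci, QuantSettings(seed_check=False))
        for mature_id, v in on.counts.items():
            assert v <= off.counts[mature_id]

    def test_planted_truth_recovered_exactly(self, quantified, reference):
        _, _, quant, manifest = quantified
        for mature_id, expected in manifest.expected_counts_per_mature.items():
            assert quant.counts[mature_id] == expected


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(Fraction(5, 2), 3), (Fraction(10, 3), 3), (Fraction(0), 0),
         (Fraction(7, 2), 4), (Fraction(-5, 2), -3)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected

    def test_round_table_cells(self):
        table = {"a": {"l1": Fraction(5, 2), "l2": Fraction(1, 3)}}
        assert round_table(table) == {"a": {"l1": 3, "l2": 0}}


class TestFamilyCounts:
    def _table(self):
        t = QuantTable()
        from mirvar.quantify import LibraryQuant

        t.add_library(
            "lib1",
            LibraryQuant(
                counts={"miR-1-5p": Fraction(7), "miR-2-5p": Fraction(5), "miR-9-3p": Fraction(4)},
                qualified=[], tallies={},
            ),
        )
        return t

    MAT2HP = {"miR-1-5p": "mir-1", "miR-2-5p": "mir-2", "miR-9-3p": "mir-9"}

    def test_family_aggregation(self):
        fams = family_counts(self._table(), {"fam-A": ["mir-1", "mir-2"]}, self.MAT2HP)
        assert fams["fam-A"]["lib1"] == 12

    def test_orphan_becomes_singleton_family(self):
        fams = family_counts(self._table(), {"fam-A": ["mir-1", "mir-2"]}, self.MAT2HP)
        assert fams["miR-9-3p"]["lib1"] == 4

    def test_families_partition_mature_counts(self):
        table = self._table()
        fams = family_counts(table, {"fam-A": ["mir-1", "mir-2"]}, self.MAT2HP)
        total_f = sum(v["lib1"] for v in fams.values())
        total_m = sum(row["lib1"] for row in table.fractional.values())
        assert total_f == total_m
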