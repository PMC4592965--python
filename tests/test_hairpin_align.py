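from __future__ import annotations

import numpy as np
import pytest

from oracle_align import oracle_min_penalty

from mirvar.fixtures import make_hairpin
from mirvar.formats import HairpinRecord, MatureRecord
from mirvar.hairpin_align import AlignParams, align_read, locate_matures, map_all
from mirvar.preprocess import CollapsedRead


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def hairpin():
    rng = np.random.default_rng(7)
    return HairpinRecord("h1", random_seq(rng, 70))


def substitute(seq: str, pos: int) -> str:
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return seq[:pos] + rot[seq[pos]] + seq[pos + 1 :]


class TestAlignRead:
    def test_exact_substring_single_clean_alignment(self, hairpin):
        read = hairpin.sequence[20:42]
        (aln,) = align_read(read, hairpin)
        assert (aln.start, aln.end, aln.penalty) == (20, 42, 0)
        assert aln.clip5_len == aln.clip3_len == 0
        assert aln.ops == (("=", 22),)

    def test_two_central_mismatches_at_cap(self, hairpin):
        # central positions: clipping them out would shrink the core below 15
        read = substitute(substitute(hairpin.sequence[20:42], 8), 13)
        alns = align_read(read, hairpin)
        assert alns and alns[0].penalty == 60
        assert any(a.n_mismatch == 2 for a in alns)

    def test_three_central_mismatches_over_cap(self, hairpin):
        read = hairpin.sequence[20:42]
        for pos in (8, 10, 13):
            read = substitute(read, pos)
        assert align_read(read, hairpin) == []

    def _deletion_site(self, hairpin, gap):
        # pick a site where (per the independent oracle) the planted gap is
        # the cheapest explanation, not some free-clip alternative
        hp = hairpin.sequence
        for s in range(len(hp) - 22 - gap):
            read = hp[s : s + 11] + hp[s + 11 + gap : s + 22 + gap]
            if oracle_min_penalty(read, hp) == 40 + 6 * gap:
                return read
        pytest.fail("no unambiguous deletion site in fixture hairpin")

    def test_three_base_deletion_within_cap(self, hairpin):
        read = self._deletion_site(hairpin, gap=3)
        alns = align_read(read, hairpin)
        assert alns and alns[0].penalty == 58
        assert any(a.n_del_bases == 3 for a in alns)

    def test_four_base_deletion_over_cap(self, hairpin):
        hp = hairpin.sequence
        for s in range(0, len(hp) - 26, 7):
            read = hp[s : s + 11] + hp[s + 15 : s + 26]
            alns = align_read(read, hairpin)
            # a 4-base gap costs 64 > 60: never reported as such
            assert all(a.n_del_bases != 4 for a in alns)
            assert all(a.penalty <= 60 for a in alns)

    def test_trailing_foreign_bases_clipped_free(self, hairpin):
        tail = "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[b]
            for b in hairpin.sequence[42:46]
        )
        read = hairpin.sequence[20:42] + tail
        alns = align_read(read, hairpin)
        assert alns[0].penalty == 0
        assert any(a.clip3_len == 4 for a in alns)

    def test_read_below_min_core_unalignable(self, hairpin):
        assert align_read(hairpin.sequence[0:14], hairpin) == []

    def test_no_alignment_ends_in_extendable_clip(self, hairpin):
        """Optimality: a clip adjacent to a base that would align as a free
        match is never reported (it would be a dominated sub-alignment)."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            s = int(rng.integers(0, 40))
            read = hairpin.sequence[s : s + 22]
            pos = int(rng.integers(0, 22))
            read = substitute(read, pos)
            for aln in align_read(read, hairpin):
                i0, i1 = aln.read_aligned_span
                if aln.clip5_len and aln.start > 0:
                    assert read[i0 - 1] != hairpin.sequence[aln.start - 1]
                if aln.clip3_len and aln.end < len(hairpin.sequence):
                    assert read[i1] != hairpin.sequence[aln.end]

    def test_mirror_symmetry(self, hairpin):
        rng = np.random.default_rng(9)
        for _ in range(25):
            read = substitute(random_seq(rng, 20) if rng.random() < 0.3
                              else hairpin.sequence[5:25], int(rng.integers(0, 20)))
            fwd = align_read(read, hairpin)
            rev = align_read(read[::-1], HairpinRecord("r", hairpin.sequence[::-1]))
            assert bool(fwd) == bool(rev)
            if fwd:
                assert fwd[0].penalty == rev[0].penalty


class TestOracleEquivalence:
    def test_dp_matches_bruteforce_on_random_pairs(self):
        """Minimum DP penalty equals exhaustive run-length enumeration for 500
        random (read <= 25 nt, hairpin <= 60 nt) pairs, including mutated
        substrings that sit near the penalty cap."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(500):
            n = int(rng.integers(30, 61))
            hp = random_seq(rng, n)
            style = rng.random()
            if style < 0.3:
                read = random_seq(rng, int(rng.integers(15, 26)))
            else:
                m = int(rng.integers(15, min(26, n)))
                s = int(rng.integers(0, n - m + 1))
                read = hp[s : s + m]
                for _k in range(int(rng.integers(0, 4))):
                    read = substitute(read, int(rng.integers(0, len(read))))
            expected = oracle_min_penalty(read, hp)
            alns = align_read(read, hp, hairpin_id="h")
            got = alns[0].penalty if alns else None
            assert got == expected, (read, hp)
            n_checked += 1
        assert n_checked == 500


class TestMapAll:
    def test_best_hairpin_wins(self, hairpin):
        other = HairpinRecord("h2", substitute(hairpin.sequence, 30))
        read = CollapsedRead("1-5", hairpin.sequence[20:42], 5)
        mappings, stats = map_all([read], [hairpin, other])
        hits = mappings["1-5"]
        assert {a.hairpin_id for a in hits} == {"h1"}
        assert stats["perfect"] == 5

    def test_perfect_tie_keeps_both(self, hairpin):
        twin = HairpinRecord("twin", hairpin.sequence)
        read = CollapsedRead("1-4", hairpin.sequence[20:42], 4)
        mappings, _ = map_all([read], [hairpin, twin])
        assert {a.hairpin_id for a in mappings["1-4"]} == {"h1", "twin"}
        assert len({a.penalty for a in mappings["1-4"]}) == 1

    def test_unmapped_read(self, hairpin):
        rng = np.random.default_rng(13)
        read = CollapsedRead("1-1", random_seq(rng, 22), 1)
        mappings, stats = map_all([read], [hairpin])
        assert mappings["1-1"] == []
        assert stats["unmapped"] == 1


class TestLocateMatures:
    def test_substring_coordinates_and_arms(self):
        hp, m5, m3 = make_hairpin(seed=1, index=1, arm_len=22, loop_len=12)
        loci = locate_matures([m5, m3], [hp])
        by_id = {l.mature_id: l for l in loci}
        assert by_id["syn-miR-1-5p"].start == 0
        assert by_id["syn-miR-1-5p"].end == 22
        assert by_id["syn-miR-1-5p"].arm == "5p"
        assert by_id["syn-miR-1-3p"].start == 34
        assert by_id["syn-miR-1-3p"].arm == "3p"

    def test_pairing_by_shared_stem(self):
        hp, m5, _ = make_hairpin(seed=2, index=9)
        other_hp, _, _ = make_hairpin(seed=4, index=8)
        loci = locate_matures([m5], [other_hp, hp])
        assert [l.hairpin_id for l in loci] == ["syn-mir-9"]

    def test_mature_absent_from_hairpin_excluded(self, caplog):
        hp, _, _ = make_hairpin(seed=5, index=2)
        stray = MatureRecord("syn-miR-2-5p", "T" * 22)
        assert locate_matures([stray], [hp]) == []
        assert "not found" in caplog.text

    def test_duplicate_occurrence_takes_first_with_warning(self, caplog):
        hp = HairpinRecord("syn-mir-3", "ACGTACGTACGTACGTA" + "ACGTACGTACGTACGTA")
        mat = MatureRecord("syn-miR-3", "ACGTACGTACGTACGT")
        (locus,) = locate_matures([mat], [hp])
        assert locus.start == 0
        assert "occurs" in caplog.text
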