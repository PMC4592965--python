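"""Known-miRNA quantification from hairpin mappings.

The pipeline is: position check (end shifts vs the canonical mature of at most
``max_shift`` nt), optional seed-region check (read positions 2-8 must align to
the canonical seed as exact matches, with no 5' clip and no 5' shift), then
count assignment.  A read with a single qualified mapping contributes its whole
count; a multi-mapping read first keeps only its best-priority mappings (the
qualified mappings with the fewest soft-clipped bases) and its count is divided
evenly over them, so the total number of counted reads is conserved exactly —
counts are accumulated as rationals and only rounded on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from mirvar.hairpin_align import HairpinAlignment, MatureLocus
from mirvar.preprocess import CollapsedRead


@dataclass(frozen=True)
class QuantSettings:
    max_shift: int = 3
    seed_check: bool = True
    # seed span: read positions 2-8 inclusive, 1-based
    seed_start: int = 2
    seed_end: int = 8


@dataclass(frozen=True)
class QualifiedMapping:
    """One qualified (position/seed-passing) mapping with its count share."""

    read_uid: str
    count: int
    share: Fraction
    alignment: HairpinAlignment
    locus: MatureLocus
    shift5: int
    shift3: int


@dataclass
class LibraryQuant:
    """Quantification result for one library."""

    counts: dict[str, Fraction]
    qualified: list[QualifiedMapping]
    tallies: dict[str, int]

    def total(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))


def position_check(
    alignment: HairpinAlignment,
    loci: Sequence[MatureLocus],
    max_shift: int = 3,
) -> tuple[MatureLocus, int, int] | None:
    """Match an alignment to the best canonical mature locus on its hairpin.

    A locus passes when both end shifts of the aligned core (clips excluded)
    are within ``max_shift``; among passing loci the one with minimal total
    absolute shift wins, ties going to the 5p arm.  Returns (locus, shift5,
    shift3) or None.
    """
    best: tuple[MatureLocus, int, int] | None = None
    best_key: tuple[int, int] | None = None
    for locus in loci:
        if locus.hairpin_id != alignment.hairpin_id:
            continue
        shift5 = alignment.start - locus.start
        shift3 = alignment.end - locus.end
        if abs(shift5) > max_shift or abs(shift3) > max_shift:
            continue
        key = (abs(shift5) + abs(shift3), 0 if locus.arm == "5p" else 1)
        if best_key is None or key < best_key:
            best_key = key
            best = (locus, shift5, shift3)
    return best


def seed_check(
    read_sequence: str,
    alignment: HairpinAlignment,
    locus: MatureLocus,
    hairpin_sequence: str,
    settings: QuantSettings = QuantSettings(),
) -> bool:
    """True when the read carries the canonical seed exactly.

    Requires no 5' soft clip, the aligned start exactly on the locus start, and
    read positions 2-8 (1-based) aligned to the corresponding hairpin bases as
    matches only — any mismatch, insertion or deletion touching the window
    fails.
    """
    if alignment.clip5_len != 0:
        return False
    if alignment.start != locus.start:
        return False
    lo = settings.seed_start  # 1-based window [lo, hi]
    hi = settings.seed_end
    read_pos = 0  # 0-based, bases consumed
    for op, n in alignment.ops:
        if op == "S":
            read_pos += n
            continue
        if op in ("=", "X", "I"):
            span_lo, span_hi = read_pos + 1, read_pos + n  # 1-based positions covered
            if span_lo <= hi and span_hi >= lo and op != "=":
                return False
            read_pos += n
        elif op == "D":
            # a deletion between read positions p and p+1 shifts the
            # read/hairpin correspondence for every later window position
            if 1 <= read_pos < hi:
                return False
    return True


def qualify_mappings(
    read_sequence: str,
    alignments: Sequence[HairpinAlignment],
    loci_by_hairpin: Mapping[str, Sequence[MatureLocus]],
    hairpin_seqs: Mapping[str, str],
    settings: QuantSettings = QuantSettings(),
) -> tuple[list[tuple[HairpinAlignment, MatureLocus, int, int]], str]:
    """Filter one read's mapping set by position (and seed) checks.

    Returns (qualified mappings, failure stage) where the stage is '' when at
    least one mapping qualified, else 'position' or 'seed'.
    """
    passed_position = []
    for aln in alignments:
        loci = loci_by_hairpin.get(aln.hairpin_id, ())
        hit = position_check(aln, loci, settings.max_shift)
        if hit is not None:
            passed_position.append((aln, *hit))
    if not passed_position:
        return [], "position"
    if not settings.seed_check:
        return passed_position, ""
    qualified = [
        (aln, locus, s5, s3)
        for aln, locus, s5, s3 in passed_position
        if seed_check(read_sequence, aln, locus, hairpin_seqs[aln.hairpin_id], settings)
    ]
    return (qualified, "") if qualified else ([], "seed")


def assign_counts(
    reads: Sequence[CollapsedRead],
    mappings: Mapping[str, Sequence[HairpinAlignment]],
    loci: Sequence[MatureLocus],
    hairpin_seqs: Mapping[str, str],
    settings: QuantSettings = QuantSettings(),
) -> LibraryQuant:
    """Quantify one library's collapsed reads against canonical mature loci.

    Every mature with a locus appears in the output (zero when unobserved).
    The tallies record read counts at each stage: mapped, passed_position,
    passed_seed, counted, multi_mapped, failed_position, failed_seed.
    """
    loci_by_hairpin: dict[str, list[MatureLocus]] = {}
    for locus in loci:
        loci_by_hairpin.setdefault(locus.hairpin_id, []).append(locus)
    counts: dict[str, Fraction] = {l.mature_id: Fraction(0) for l in loci}
    qualified_out: list[QualifiedMapping] = []
    tallies = {
        "total": 0, "mapped": 0, "passed_position": 0, "passed_seed": 0,
        "counted": 0, "multi_mapped": 0, "failed_position": 0, "failed_seed": 0,
        "unmapped": 0,
    }
    for cread in reads:
        tallies["total"] += cread.count
        alns = mappings.get(cread.uid, ())
        if not alns:
            tallies["unmapped"] += cread.count
            continue
        tallies["mapped"] += cread.count
        qualified, stage = qualify_mappings(
            cread.sequence, alns, loci_by_hairpin, hairpin_seqs, settings
        )
        if stage == "position":
            tallies["failed_position"] += cread.count
            continue
        tallies["passed_position"] += cread.count
        if stage == "seed":
            tallies["failed_seed"] += cread.count
            continue
        tallies["passed_seed"] += cread.count
        # best priority: minimum total soft-clipped bases
        min_clips = min(a.clip5_len + a.clip3_len for a, _, _, _ in qualified)
        best = [q for q in qualified if q[0].clip5_len + q[0].clip3_len == min_clips]
        share = Fraction(cread.count, len(best))
        if len(best) > 1:
            tallies["multi_mapped"] += cread.count
        tallies["counted"] += cread.count
        for aln, locus, s5, s3 in best:
            counts[locus.mature_id] += share
            qualified_out.append(
                QualifiedMapping(
                    read_uid=cread.uid, count=cread.count, share=share,
                    alignment=aln, locus=locus, shift5=s5, shift3=s3,
                )
            )
    return LibraryQuant(counts=counts, qualified=qualified_out, tallies=tallies)


def round_half_away(value: Fraction) -> int:
    """Round half away from zero on an exact rational."""
    if value >= 0:
        return int(value + Fraction(1, 2))
    return -round_half_away(-value)


def round_table(
    table: Mapping[str, Mapping[str, Fraction]]
) -> dict[str, dict[str, int]]:
    """Round every fractional cell half-away-from-zero to an integer table."""
    return {
        row_id: {lib: round_half_away(v) for lib, v in row.items()}
        for row_id, row in table.items()
    }


class QuantTable:
    """Mature x library count table with exact fractional cells.

    Built by adding one :class:`LibraryQuant` per library; ``fractional`` maps
    mature id -> {library: Fraction} and ``rounded()`` produces the integer
    table written to CSV.
    """

    def __init__(self) -> None:
        self.fractional: dict[str, dict[str, Fraction]] = {}
        self.libraries: list[str] = []
        self.tallies: dict[str, dict[str, int]] = {}

    def add_library(self, name: str, quant: LibraryQuant) -> None:
        if name in self.libraries:
            raise ValueError(f"duplicate library name {name!r}")
        self.libraries.append(name)
        self.tallies[name] = quant.tallies
        for mature_id, value in quant.counts.items():
            self.fractional.setdefault(mature_id, {})[name] = value
        for row in self.fractional.values():
            row.setdefault(name, Fraction(0))

    def rounded(self) -> dict[str, dict[str, int]]:
        return round_table(self.fractional)


def family_counts(
    table: QuantTable,
    families: Mapping[str, Sequence[str]],
    mature_to_hairpin: Mapping[str, str],
) -> dict[str, dict[str, Fraction]]:
    """Aggregate mature counts into family counts.

    A family's count is the sum over matures whose hairpin belongs to it;
    matures whose hairpin is in no family form singleton families named by the
    mature id.  Family counts therefore partition the mature counts exactly.
    """
    hairpin_to_family: dict[str, str] = {}
    for fam, members in families.items():
        for m in members:
            hairpin_to_family[m.lower()] = fam
    out: dict[str, dict[str, Fraction]] = {}
    for mature_id, row in table.fractional.items():
        hairpin_id = mature_to_hairpin.get(mature_id, "")
        fam = hairpin_to_family.get(hairpin_id.lower(), mature_id)
        dest = out.setdefault(fam, {})
        for lib, v in row.items():
            dest[lib] = dest.get(lib, Fraction(0)) + v
    return out
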