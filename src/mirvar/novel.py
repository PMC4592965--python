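"""Novel pre-miRNA candidate generation from genome read stacks.

The procedure nominates candidate precursors from piles of perfectly mapped
reads: (1) perfect genome mappings of collapsed reads are filtered to mapped
lengths 18-25 nt and at most 5 loci per read, then merged into read stacks;
(2) each stack is excised in both orientations with a short flank on the
mature side and a long flank on the loop side; (3) collapsed reads and known
matures are re-mapped perfectly onto each candidate as its signature;
(4) the candidate's mature is the top signature stack, accepted only when its
read count is more than twice the second stack's; (5) an optional external
scoring backend (secondary-structure folding plus a hairpin score) filters
candidates, which otherwise pass through unscored.  Candidate identity across
libraries is genomic coordinates, and naming follows
"<species>-novel-mir-<n>" / "<species>-novel-miR-<n>".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

from mirvar.formats import MatureRecord, revcomp
from mirvar.hairpin_align import HairpinAlignment, MatureLocus
from mirvar.preprocess import CollapsedRead
from mirvar.quantify import QuantSettings, assign_counts, LibraryQuant

logger = logging.getLogger(__name__)

# backend: sequence -> (dot_bracket structure or None, score)
ScoreBackend = Callable[[str], tuple[str | None, float]]


@dataclass(frozen=True)
class PerfectMapping:
    """One perfect (exact substring) genome mapping of a collapsed read."""

    read_uid: str
    count: int
    sequence: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class GenomeStack:
    chrom: str
    strand: str
    start: int
    end: int
    read_uids: tuple[str, ...]
    count: int


@dataclass(frozen=True)
class NovelMature:
    name: str
    sequence: str
    seed_match: str | None = None


@dataclass(frozen=True)
class NovelPrecursor:
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    mature: NovelMature | None = None
    dot_bracket: str | None = None
    score: float | None = None
    status: str = "unscored"  # 'unscored' | 'scored'

    @property
    def coordinate_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def location(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def map_perfect(
    reads: Sequence[CollapsedRead],
    genome: Mapping[str, str],
    min_len: int = 18,
    max_len: int = 25,
    max_loci: int = 5,
) -> list[PerfectMapping]:
    """Perfect genome mappings of collapsed reads, filtered for stacking.

    Exact substring search on both strands; reads outside [min_len, max_len]
    or with more than ``max_loci`` perfect loci are discarded.
    """
    out: list[PerfectMapping] = []
    for cread in reads:
        if not (min_len <= len(cread.sequence) <= max_len):
            continue
        hits: list[PerfectMapping] = []
        for strand, query in (("+", cread.sequence), ("-", revcomp(cread.sequence))):
            for chrom in sorted(genome):
                seq = genome[chrom]
                pos = seq.find(query)
                while pos != -1:
                    hits.append(
                        PerfectMapping(
                            read_uid=cread.uid, count=cread.count, sequence=cread.sequence,
                            chrom=chrom, strand=strand, start=pos, end=pos + len(query),
                        )
                    )
                    pos = seq.find(query, pos + 1)
        if 0 < len(hits) <= max_loci:
            out.extend(hits)
    return out


def build_stacks(mappings: Iterable[PerfectMapping]) -> list[GenomeStack]:
    """Merge perfect mappings into stacks by coordinate overlap per strand."""
    by_group: dict[tuple[str, str], list[PerfectMapping]] = {}
    for m in mappings:
        by_group.setdefault((m.chrom, m.strand), []).append(m)
    stacks: list[GenomeStack] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda m: (m.start, m.end))
        cur_start, cur_end = group[0].start, group[0].end
        members: list[PerfectMapping] = []
        for m in group + [None]:  # type: ignore[list-item]
            if m is not None and m.start < cur_end:
                members.append(m)
                cur_end = max(cur_end, m.end)
            else:
                stacks.append(
                    GenomeStack(
                        chrom=chrom, strand=strand, start=cur_start, end=cur_end,
                        read_uids=tuple(x.read_uid for x in members),
                        count=sum(x.count for x in members),
                    )
                )
                if m is not None:
                    cur_start, cur_end = m.start, m.end
                    members = [m]
        if not members:
            stacks.pop()  # guard against empty trailing stack (cannot happen)
    return stacks


def excise_candidates(
    genome: Mapping[str, str],
    stack: GenomeStack,
    mature_flank: int = 10,
    loop_flank: int = 70,
) -> list[NovelPrecursor]:
    """Excise up to two candidate precursor windows around a read stack.

    Candidate A assumes the stack is the 5'-side mature ([start - mature_flank,
    end + loop_flank)); candidate B the 3'-side ([start - loop_flank,
    end + mature_flank)); both are clipped at chromosome bounds, and
    minus-strand stacks are excised from the reverse complement.
    """
    chrom_seq = genome[stack.chrom]
    n = len(chrom_seq)
    windows = [
        (max(0, stack.start - mature_flank), min(n, stack.end + loop_flank)),
        (max(0, stack.start - loop_flank), min(n, stack.end + mature_flank)),
    ]
    out = []
    seen: set[tuple[int, int]] = set()
    for start, end in windows:
        if (start, end) in seen:
            continue
        seen.add((start, end))
        seq = chrom_seq[start:end]
        if stack.strand == "-":
            seq = revcomp(seq)
        out.append(
            NovelPrecursor(
                name="", chrom=stack.chrom, strand=stack.strand,
                start=start, end=end, sequence=seq,
            )
        )
    return out


@dataclass(frozen=True)
class SignatureHit:
    """One perfect mapping onto a candidate precursor."""

    read_uid: str
    count: int
    sequence: str
    start: int
    end: int
    is_known_mature: bool = False


def build_signature(
    reads: Sequence[CollapsedRead],
    known_matures: Sequence[MatureRecord],
    candidate: NovelPrecursor,
    min_len: int = 18,
    max_len: int = 25,
) -> list[SignatureHit]:
    """Perfect mappings of reads (length 18-25) and known matures onto a candidate.

    No mismatches are permitted (stricter than a 1-mismatch signature, to cut
    false positives); each occurrence of a sequence yields one hit.
    """
    hits: list[SignatureHit] = []

    def occurrences(query: str) -> list[int]:
        found, pos = [], candidate.sequence.find(query)
        while pos != -1:
            found.append(pos)
            pos = candidate.sequence.find(query, pos + 1)
        return found

    for cread in reads:
        if not (min_len <= len(cread.sequence) <= max_len):
            continue
        for pos in occurrences(cread.sequence):
            hits.append(
                SignatureHit(cread.uid, cread.count, cread.sequence, pos, pos + len(cread.sequence))
            )
    for mat in known_matures:
        for pos in occurrences(mat.sequence):
            hits.append(
                SignatureHit(mat.mature_id, 0, mat.sequence, pos, pos + len(mat.sequence), True)
            )
    hits.sort(key=lambda h: (h.start, h.end, h.read_uid))
    return hits


def select_mature(
    candidate: NovelPrecursor, signature: Sequence[SignatureHit], fold: float = 2
) -> str | None:
    """Mature sequence from the top signature read stack, or None to discard.

    Signature reads are grouped into stacks by identical (start, end); the top
    stack's sequence is the mature iff its summed read count is strictly more
    than ``fold`` times the second stack's (a lone stack is accepted when its
    count is positive).  Known-mature hits locate but never count.
    """
    stacks: dict[tuple[int, int], dict] = {}
    for hit in signature:
        if hit.is_known_mature:
            continue
        entry = stacks.setdefault((hit.start, hit.end), {"count": 0, "seq": hit.sequence})
        entry["count"] += hit.count
    ranked = sorted(
        stacks.items(), key=lambda kv: (-kv[1]["count"], kv[0])
    )
    if not ranked or ranked[0][1]["count"] <= 0:
        return None
    top = ranked[0][1]
    second_count = ranked[1][1]["count"] if len(ranked) > 1 else 0
    if top["count"] > fold * second_count:
        return top["seq"]
    return None


def score_candidates(
    candidates: Sequence[NovelPrecursor], backend: ScoreBackend | None = None
) -> list[NovelPrecursor]:
    """Apply the pluggable scoring backend; keep candidates with score > 0.

    Without a backend every candidate passes through marked 'unscored'.  With
    a backend returning (structure, score), candidates scoring <= 0 are
    dropped; when a structure is returned, candidates whose mature base-pairs
    with itself (i.e. the mature is not confined to one arm) are dropped too.
    """
    out = []
    for cand in candidates:
        if backend is None:
            out.append(cand)
            continue
        structure, score = backend(cand.sequence)
        if score <= 0:
            continue
        if structure is not None and cand.mature is not None:
            pos = cand.sequence.find(cand.mature.sequence)
            if pos != -1 and _mature_self_paired(structure, pos, pos + len(cand.mature.sequence)):
                continue
        out.append(replace(cand, dot_bracket=structure, score=score, status="scored"))
    return out


def _mature_self_paired(structure: str, start: int, end: int) -> bool:
    """True when any base inside [start, end) pairs with another base inside it."""
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            if start <= i < end and start <= j < end:
                return True
    return False


def seed_match(mature_seq: str, known_matures: Sequence[MatureRecord]) -> str | None:
    """Known mature with an identical seed (positions 2-8, 1-based), if any."""
    seed = mature_seq[1:8]
    if len(seed) < 7:
        return None
    for mat in sorted(known_matures, key=lambda m: m.mature_id):
        if mat.sequence[1:8] == seed:
            return mat.mature_id
    return None


def predict_library(
    reads: Sequence[CollapsedRead],
    genome: Mapping[str, str],
    known_matures: Sequence[MatureRecord] = (),
    backend: ScoreBackend | None = None,
    min_len: int = 18,
    max_len: int = 25,
    max_loci: int = 5,
    fold: float = 2,
    mature_flank: int = 10,
    loop_flank: int = 70,
) -> list[NovelPrecursor]:
    """Run stack -> excision -> signature -> mature selection for one library.

    Of the two excision orientations for a stack, candidates that fail mature
    selection are dropped; when both orientations survive with the same mature
    the one whose window places the stack on the 5' side is kept.
    """
    mappings = map_perfect(reads, genome, min_len, max_len, max_loci)
    candidates: list[NovelPrecursor] = []
    for stack in build_stacks(mappings):
        for cand in excise_candidates(genome, stack, mature_flank, loop_flank):
            signature = build_signature(reads, known_matures, cand, min_len, max_len)
            mature_seq = select_mature(cand, signature, fold)
            if mature_seq is None:
                continue
            candidates.append(
                replace(cand, mature=NovelMature(name="", sequence=mature_seq))
            )
            break  # first surviving orientation wins for this stack
    return score_candidates(candidates, backend)


def unify_names(
    per_library: Mapping[str, Sequence[NovelPrecursor]],
    species: str,
) -> tuple[list[NovelPrecursor], dict[str, NovelMature], dict[str, set[str]]]:
    """Unify candidate names across libraries by genomic coordinates.

    Precursors with identical (chrom, start, end, strand) are the same
    precursor; matures with the same precursor and identical sequence are the
    same mature.  Numbering follows genomic sort order (chrom, start, strand)
    and is invariant to library input order.  Returns (named precursors,
    {mature name: mature}, {mature name: libraries observed in}).
    """
    by_coord: dict[tuple[str, int, int, str], list[tuple[str, NovelPrecursor]]] = {}
    for lib in sorted(per_library):
        for cand in per_library[lib]:
            by_coord.setdefault(cand.coordinate_key, []).append((lib, cand))
    ordered = sorted(by_coord, key=lambda k: (k[0], k[1], k[3]))
    precursors: list[NovelPrecursor] = []
    matures: dict[str, NovelMature] = {}
    observed: dict[str, set[str]] = {}
    for number, key in enumerate(ordered, 1):
        entries = by_coord[key]
        prototype = entries[0][1]
        name = f"{species}-novel-mir-{number}"
        precursors.append(replace(prototype, name=name))
        seqs: dict[str, set[str]] = {}
        for lib, cand in entries:
            if cand.mature is not None:
                seqs.setdefault(cand.mature.sequence, set()).add(lib)
        for k, seq in enumerate(sorted(seqs)):
            suffix = "" if len(seqs) == 1 else chr(ord("a") + k)
            mat_name = f"{species}-novel-miR-{number}{suffix}"
            matures[mat_name] = NovelMature(name=mat_name, sequence=seq)
            observed[mat_name] = seqs[seq]
    return precursors, matures, observed


def attach_seed_matches(
    matures: Mapping[str, NovelMature], known_matures: Sequence[MatureRecord]
) -> dict[str, NovelMature]:
    return {
        name: replace(mat, seed_match=seed_match(mat.sequence, known_matures))
        for name, mat in matures.items()
    }


def quantify_novel(
    reads: Sequence[CollapsedRead],
    precursors: Sequence[NovelPrecursor],
    matures: Mapping[str, NovelMature],
    settings: QuantSettings = QuantSettings(),
) -> LibraryQuant:
    """Quantify novel matures in one library, perfect precursor mappings only.

    Collapsed reads are matched to novel precursors by exact substring
    occurrence (penalty 0, no clips); the resulting mappings then pass through
    the same position/seed checks and even count division as known miRNAs.
    """
    loci: list[MatureLocus] = []
    hairpin_seqs: dict[str, str] = {}
    for prec in precursors:
        hairpin_seqs[prec.name] = prec.sequence
        for mat_name, mat in matures.items():
            if _stem_number(mat_name) != _stem_number(prec.name):
                continue
            pos = prec.sequence.find(mat.sequence)
            if pos == -1:
                continue
            end = pos + len(mat.sequence)
            arm = "5p" if (pos + end) / 2 < len(prec.sequence) / 2 else "3p"
            loci.append(MatureLocus(mat_name, prec.name, pos, end, arm))
    mappings: dict[str, list[HairpinAlignment]] = {}
    for cread in reads:
        hits: list[HairpinAlignment] = []
        for prec in precursors:
            pos = prec.sequence.find(cread.sequence)
            while pos != -1:
                m = len(cread.sequence)
                hits.append(
                    HairpinAlignment(
                        read_uid=cread.uid, hairpin_id=prec.name,
                        start=pos, end=pos + m, ops=(("=", m),),
                        penalty=0, n_mismatch=0, n_ins_bases=0, n_del_bases=0,
                        clip5_len=0, clip3_len=0,
                    )
                )
                pos = prec.sequence.find(cread.sequence, pos + 1)
        mappings[cread.uid] = hits
    return assign_counts(reads, mappings, loci, hairpin_seqs, settings)


def _stem_number(name: str) -> str:
    """Numeric stem of a unified novel name ('hsa-novel-miR-7a' -> '7')."""
    tail = name.rsplit("-", 1)[-1]
    digits = "".join(ch for ch in tail if ch.isdigit())
    return digits
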