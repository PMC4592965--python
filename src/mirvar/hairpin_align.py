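"""Penalty-capped semi-global alignment of collapsed reads against hairpins.

Scoring follows a short-read mapper's penalty model: mismatches cost
``mismatch`` (default 30), a gap of length L costs ``gap_open + gap_extend*L``
(default 40 + 6L), terminal soft clips on the read are free, and alignments
with total penalty above ``cap`` (default 60) are not reported.  Under the
defaults an alignment can therefore contain at most 2 mismatches (60) or one
gap of at most 3 bases (40 + 18 = 58), never both.

Every alignment tied at the minimum penalty is reported, across hairpins and
across loci within a hairpin.  Soft clips are canonical: a terminal read base
is clipped only when aligning it would cost a mismatch or run past the hairpin
end, so equal-penalty sub-alignments of a longer match are never enumerated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mirvar.formats import HairpinRecord, MatureRecord
from mirvar.preprocess import CollapsedRead

logger = logging.getLogger(__name__)

# op codes: '=' match, 'X' mismatch, 'I' insertion (read-only base),
# 'D' deletion (hairpin-only base), 'S' soft clip (first/last run only)
Ops = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class AlignParams:
    mismatch: int = 30
    gap_open: int = 40
    gap_extend: int = 6
    cap: int = 60
    min_core: int = 15
    max_ties: int = 200


@dataclass(frozen=True)
class HairpinAlignment:
    """One read-to-hairpin alignment (coordinates 0-based half-open, clips excluded)."""

    read_uid: str
    hairpin_id: str
    start: int
    end: int
    ops: Ops
    penalty: int
    n_mismatch: int
    n_ins_bases: int
    n_del_bases: int
    clip5_len: int
    clip3_len: int
    n_n_bases: int = 0

    @property
    def read_aligned_span(self) -> tuple[int, int]:
        """(first, last+1) read positions inside the aligned core."""
        consumed = sum(n for op, n in self.ops if op in ("=", "X", "I", "S"))
        return self.clip5_len, consumed - self.clip3_len

    def category(self) -> str:
        """Mapping category for summary statistics."""
        if self.clip5_len and self.clip3_len:
            return "both_clips"
        if self.n_mismatch:
            return "mismatch"
        if self.n_ins_bases:
            return "insertion"
        if self.n_del_bases:
            return "deletion"
        if self.clip5_len:
            return "clip5"
        if self.clip3_len:
            return "clip3"
        return "perfect"


def _subcost(a: str, b: str, mismatch: int) -> int:
    if a == b and a != "N":
        return 0
    return mismatch


def align_read(
    sequence: str, hairpin: HairpinRecord | str, params: AlignParams = AlignParams(),
    read_uid: str = "", hairpin_id: str | None = None,
) -> list[HairpinAlignment]:
    """All minimum-penalty alignments of ``sequence`` against one hairpin.

    Returns every distinct optimal alignment with penalty <= ``params.cap`` and
    an aligned core of at least ``params.min_core`` read bases; an empty list
    means the read is unalignable to this hairpin.  Sense strand only.
    """
    if isinstance(hairpin, HairpinRecord):
        href, hid = hairpin.sequence, hairpin.hairpin_id
    else:
        href, hid = hairpin, hairpin_id or ""
    read = sequence.upper()
    m, n = len(read), len(href)
    if m < params.min_core or n == 0:
        return []

    cap = params.cap
    mism = params.mismatch
    open_cost = params.gap_open + params.gap_extend
    ext = params.gap_extend

    # dp[state][i][j]: dict cost -> max core length (read bases consumed since
    # the fresh start).  i = read bases consumed (1..m), j = hairpin position.
    # States: 0 = diagonal (match/mismatch), 1 = insertion, 2 = deletion.
    M: list[list[dict[int, int]]] = [[{} for _ in range(n + 1)] for _ in range(m + 1)]
    I: list[list[dict[int, int]]] = [[{} for _ in range(n + 1)] for _ in range(m + 1)]
    D: list[list[dict[int, int]]] = [[{} for _ in range(n + 1)] for _ in range(m + 1)]

    def upd(cell: dict[int, int], cost: int, core: int) -> None:
        if cost <= cap and core > cell.get(cost, -1):
            cell[cost] = core

    def start_ok(i: int, j: int) -> bool:
        # clip5 = i-1: a 5' clip is canonical only when the adjacent clipped
        # base could not extend the core as a free match
        if i == 1:
            return True
        if j == 1:
            return True
        return _subcost(read[i - 2], href[j - 2], 1) != 0

    for i in range(1, m + 1):
        ri = read[i - 1]
        Mi, Ii, Di = M[i], I[i], D[i]
        Mp, Ip, Dp = M[i - 1], I[i - 1], D[i - 1]
        for j in range(1, n + 1):
            s = _subcost(ri, href[j - 1], mism)
            cell = Mi[j]
            if s <= cap and start_ok(i, j):
                upd(cell, s, 1)
            for prev in (Mp[j - 1], Ip[j - 1], Dp[j - 1]):
                for cost, core in prev.items():
                    upd(cell, cost + s, core + 1)
            # insertion: read base i-1 consumed, no hairpin base
            icell = Ii[j]
            for cost, core in Mp[j].items():
                upd(icell, cost + open_cost, core + 1)
            for cost, core in Ip[j].items():
                upd(icell, cost + ext, core + 1)
            # deletion: hairpin base j-1 consumed, no read base
            dcell = Di[j]
            for cost, core in Mi[j - 1].items():
                upd(dcell, cost + open_cost, core)
            for cost, core in Di[j - 1].items():
                upd(dcell, cost + ext, core)

    def end_ok(i: int, j: int) -> bool:
        # clip3 = m-i canonical only when extension is not a free match
        if i == m or j == n:
            return True
        return _subcost(read[i], href[j], 1) != 0

    best = None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if not end_ok(i, j):
                continue
            for cost, core in M[i][j].items():
                if core >= params.min_core and (best is None or cost < best):
                    best = cost
    if best is None:
        return []

    # enumerate all optimal paths by backward DFS over the dp dicts
    results: list[HairpinAlignment] = []
    seen: set[tuple[int, Ops]] = set()
    truncated = False

    def emit(end_i: int, end_j: int, path: list[str]) -> None:
        nonlocal truncated
        # path is backward list of op chars from the end cell to the start
        core_ops = path[::-1]
        start_i = end_i - sum(1 for op in core_ops if op in "=XI")
        start_j = end_j - sum(1 for op in core_ops if op in "=XD")
        clip5, clip3 = start_i, m - end_i
        runs: list[tuple[str, int]] = []
        if clip5:
            runs.append(("S", clip5))
        for op in core_ops:
            if runs and runs[-1][0] == op:
                runs[-1] = (op, runs[-1][1] + 1)
            else:
                runs.append((op, 1))
        if clip3:
            runs.append(("S", clip3))
        ops = tuple(runs)
        key = (start_j, ops)
        if key in seen:
            return
        if len(results) >= params.max_ties:
            truncated = True
            return
        seen.add(key)
        results.append(
            HairpinAlignment(
                read_uid=read_uid,
                hairpin_id=hid,
                start=start_j,
                end=end_j,
                ops=ops,
                penalty=best,
                n_mismatch=sum(1 for op in core_ops if op == "X"),
                n_ins_bases=sum(1 for op in core_ops if op == "I"),
                n_del_bases=sum(1 for op in core_ops if op == "D"),
                clip5_len=clip5,
                clip3_len=clip3,
                n_n_bases=sum(1 for c in read[start_i:end_i] if c == "N"),
            )
        )

    def walk(state: str, i: int, j: int, cost: int, path: list[str], end: tuple[int, int]) -> None:
        if truncated:
            return
        if state == "M":
            s = _subcost(read[i - 1], href[j - 1], mism)
            rem = cost - s
            if rem < 0:
                return
            op = "=" if s == 0 else "X"
            path.append(op)
            if rem == 0 and start_ok(i, j):
                core = end[0] - (i - 1)
                if core >= params.min_core:
                    emit(end[0], end[1], path)
            for pstate, cell in (("M", M[i - 1][j - 1]), ("I", I[i - 1][j - 1]), ("D", D[i - 1][j - 1])):
                if rem in cell and i > 1 and j > 1:
                    walk(pstate, i - 1, j - 1, rem, path, end)
            path.pop()
        elif state == "I":
            path.append("I")
            if cost - open_cost >= 0 and (cost - open_cost) in M[i - 1][j]:
                walk("M", i - 1, j, cost - open_cost, path, end)
            if cost - ext >= 0 and (cost - ext) in I[i - 1][j]:
                walk("I", i - 1, j, cost - ext, path, end)
            path.pop()
        else:
            path.append("D")
            if cost - open_cost >= 0 and (cost - open_cost) in M[i][j - 1]:
                walk("M", i, j - 1, cost - open_cost, path, end)
            if cost - ext >= 0 and (cost - ext) in D[i][j - 1]:
                walk("D", i, j - 1, cost - ext, path, end)
            path.pop()

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if best in M[i][j] and M[i][j][best] >= params.min_core and end_ok(i, j):
                walk("M", i, j, best, [], (i, j))
    if truncated:
        logger.warning("read %s: > %d tied optimal alignments; truncated", read_uid, params.max_ties)
    results.sort(key=lambda a: (a.hairpin_id, a.start, a.ops))
    return results


def map_all(
    reads: Sequence[CollapsedRead],
    hairpins: Sequence[HairpinRecord],
    params: AlignParams = AlignParams(),
) -> tuple[dict[str, list[HairpinAlignment]], dict[str, int]]:
    """Map every collapsed read against every hairpin, keeping global best ties.

    Returns ({read uid: alignments tied at that read's minimum penalty across
    all hairpins}, mapping statistics).  An empty list means unmapped.  The
    statistics tally reads (weighted by collapsed counts) as perfect /
    mismatch / insertion / deletion / clip5 / clip3 / both_clips / unmapped by
    the category of their first-sorted best alignment.
    """
    mappings: dict[str, list[HairpinAlignment]] = {}
    stats: Counter[str] = Counter()
    for cread in reads:
        best_pen: int | None = None
        best: list[HairpinAlignment] = []
        for hp in hairpins:
            for aln in align_read(cread.sequence, hp, params, read_uid=cread.uid):
                if best_pen is None or aln.penalty < best_pen:
                    best_pen = aln.penalty
                    best = [aln]
                elif aln.penalty == best_pen:
                    best.append(aln)
        mappings[cread.uid] = best
        if not best:
            stats["unmapped"] += cread.count
        else:
            stats[best[0].category()] += cread.count
            stats["mapped"] += cread.count
    return mappings, dict(stats)


@dataclass(frozen=True)
class MatureLocus:
    """Coordinates of a canonical mature miRNA on its hairpin, with arm label."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str  # '5p' or '3p'


_ARM_SUFFIXES = ("-5p", "-3p")


def _hairpin_key(mature_id: str) -> str:
    """Pairing key: strip the arm suffix and lowercase the mir segment."""
    key = mature_id
    for suf in _ARM_SUFFIXES:
        if key.lower().endswith(suf):
            key = key[: -len(suf)]
            break
    return key.lower()


def locate_matures(
    matures: Sequence[MatureRecord], hairpins: Sequence[HairpinRecord]
) -> list[MatureLocus]:
    """Locate each mature miRNA on its paired hairpin by perfect substring match.

    Pairing requires the mature and hairpin ids to share the same stem
    (e.g. mature "mmu-miR-9-5p" with hairpin "mmu-mir-9"), case-insensitive on
    the mir/miR segment.  The arm label comes from an explicit -5p/-3p suffix
    when present, else from whether the locus midpoint falls in the 5' half of
    the hairpin.  Matures not found in their paired hairpin are excluded with a
    warning; a mature occurring more than once without an arm suffix takes the
    first occurrence with a warning.
    """
    by_key = {hp.hairpin_id.lower(): hp for hp in hairpins}
    loci: list[MatureLocus] = []
    for mat in matures:
        key = _hairpin_key(mat.mature_id)
        hp = by_key.get(key)
        if hp is None:
            logger.warning("mature %s: no paired hairpin %r in reference", mat.mature_id, key)
            continue
        starts = []
        pos = hp.sequence.find(mat.sequence)
        while pos != -1:
            starts.append(pos)
            pos = hp.sequence.find(mat.sequence, pos + 1)
        if not starts:
            logger.warning(
                "mature %s not found in hairpin %s; excluded from quantification",
                mat.mature_id, hp.hairpin_id,
            )
            continue
        suffix_arm = None
        low = mat.mature_id.lower()
        if low.endswith("-5p"):
            suffix_arm = "5p"
        elif low.endswith("-3p"):
            suffix_arm = "3p"
        chosen = starts[0]
        if len(starts) > 1:
            if suffix_arm is not None:
                half = len(hp.sequence) / 2
                wanted = [
                    s for s in starts
                    if (("5p" if (s + len(mat.sequence) / 2) < half else "3p") == suffix_arm)
                ]
                if len(wanted) == 1:
                    chosen = wanted[0]
                else:
                    logger.warning(
                        "mature %s occurs %d times in %s; using first occurrence",
                        mat.mature_id, len(starts), hp.hairpin_id,
                    )
            else:
                logger.warning(
                    "mature %s occurs %d times in %s; using first occurrence",
                    mat.mature_id, len(starts), hp.hairpin_id,
                )
        end = chosen + len(mat.sequence)
        arm = suffix_arm or ("5p" if (chosen + end) / 2 < len(hp.sequence) / 2 else "3p")
        loci.append(MatureLocus(mat.mature_id, hp.hairpin_id, chosen, end, arm))
    return loci


def write_sam(
    path: str, mappings: dict[str, list[HairpinAlignment]],
    hairpins: Sequence[HairpinRecord], sequences: dict[str, str],
) -> None:
    """Export retained hairpin mappings as SAM (soft clips as S, penalty in ZP tag)."""
    op_to_cigar = {"=": "M", "X": "M", "I": "I", "D": "D", "S": "S"}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for hp in hairpins:
            fh.write(f"@SQ\tSN:{hp.hairpin_id}\tLN:{len(hp.sequence)}\n")
        for uid, alns in mappings.items():
            seq = sequences.get(uid, "*")
            if not alns:
                fh.write(f"{uid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            for k, aln in enumerate(alns):
                cigar = "".join(f"{n}{op_to_cigar[op]}" for op, n in _merge_cigar(aln.ops))
                flag = 0 if k == 0 else 256
                fh.write(
                    f"{uid}\t{flag}\t{aln.hairpin_id}\t{aln.start + 1}\t255\t{cigar}"
                    f"\t*\t0\t0\t{seq}\t*\tZP:i:{aln.penalty}\n"
                )


def _merge_cigar(ops: Ops) -> Ops:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        code = "M" if op in ("=", "X") else op
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + n)
        else:
            merged.append((code, n))
    return tuple(merged)
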