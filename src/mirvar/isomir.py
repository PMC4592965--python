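"""Per-read isomiR calling and library-level category tabulation.

Each counted read is classified against its canonical mature locus along four
dimensions of variation: internal mismatches, indels, end shifts (super/sub at
either end), and 3' non-templated nucleotide addition (NTA, read as the 3'
soft-clipped bases of the optimal alignment — clipped bases either disagree
with the following hairpin bases or run past the hairpin end, so they are
non-templated by construction).  A read varying in exactly one dimension gets
that dimension's category; more than one gives 'mixture'.

3' NTA tails are classified poly(A) / poly(U) / other (the package works in DNA
space, so poly(U) is detected as poly(T) and labelled with the RNA vocabulary).
Tails of length >= 5 that match a prefix of the sequencing adapter with at most
one error are flagged as possible adapter remnants and excluded from the NTA
sub-table.  A-to-I editing is read out as reads whose mismatches are purely
hairpin-A/read-G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from mirvar.hairpin_align import HairpinAlignment, MatureLocus
from mirvar.quantify import QualifiedMapping

CATEGORIES = (
    "canonical", "mismatch", "insertion", "deletion",
    "super5", "sub5", "super3", "sub3", "nta3", "nta5", "mixture",
)


@dataclass(frozen=True)
class IsomiRRecord:
    read_uid: str
    mature_id: str
    shift5: int
    shift3: int
    n_mismatch: int
    n_ins: int
    n_del: int
    mismatch_detail: tuple[tuple[str, str, int], ...]  # (hairpin base, read base, 1-based read pos)
    nta3: str
    nta5: str
    nta_class: str  # polyA | polyU | other | none
    adapter_remnant: bool
    a_to_g_only: bool
    category: str


def _mismatch_detail(
    read_seq: str, alignment: HairpinAlignment, hairpin_seq: str
) -> tuple[tuple[str, str, int], ...]:
    detail = []
    read_pos = 0
    hp_pos = alignment.start
    for op, n in alignment.ops:
        if op == "S":
            read_pos += n
        elif op == "=":
            read_pos += n
            hp_pos += n
        elif op == "X":
            for _ in range(n):
                detail.append((hairpin_seq[hp_pos], read_seq[read_pos], read_pos + 1))
                read_pos += 1
                hp_pos += 1
        elif op == "I":
            read_pos += n
        elif op == "D":
            hp_pos += n
    return tuple(detail)


def _matches_adapter_prefix(tail: str, adapter: str, max_errors: int = 1) -> bool:
    """Edit distance of ``tail`` vs the same-length adapter prefix window."""
    if not adapter:
        return False
    m = len(tail)
    prefix = adapter[: m + max_errors]
    # banded edit distance tail vs any prefix of `prefix`
    prev = list(range(len(prefix) + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * len(prefix)
        for j in range(1, len(prefix) + 1):
            sub = prev[j - 1] + (0 if tail[i - 1] == prefix[j - 1] else 1)
            cur[j] = min(sub, cur[j - 1] + 1, prev[j] + 1)
        prev = cur
    return min(prev[max(0, m - max_errors): m + max_errors + 1]) <= max_errors


def classify_read(
    read_sequence: str,
    alignment: HairpinAlignment,
    locus: MatureLocus,
    hairpin_sequence: str,
    shift5: int,
    shift3: int,
    adapter: str | None = None,
) -> IsomiRRecord:
    """Build the :class:`IsomiRRecord` for one qualified read mapping."""
    nta3 = read_sequence[len(read_sequence) - alignment.clip3_len:] if alignment.clip3_len else ""
    nta5 = read_sequence[: alignment.clip5_len] if alignment.clip5_len else ""
    if not nta3:
        nta_class = "none"
    elif set(nta3) == {"A"}:
        nta_class = "polyA"
    elif set(nta3) == {"T"}:
        nta_class = "polyU"
    else:
        nta_class = "other"
    remnant = bool(
        adapter and len(nta3) >= 5 and _matches_adapter_prefix(nta3, adapter.upper().replace("U", "T"))
    )
    detail = _mismatch_detail(read_sequence, alignment, hairpin_sequence)
    a_to_g = (
        alignment.n_mismatch >= 1
        and alignment.n_ins_bases == 0
        and alignment.n_del_bases == 0
        and all(hb == "A" and rb == "G" for hb, rb, _ in detail)
    )
    dims = {
        "mismatch": alignment.n_mismatch > 0,
        "indel": alignment.n_ins_bases > 0 or alignment.n_del_bases > 0,
        "shift": shift5 != 0 or shift3 != 0,
        "nta": bool(nta3) or bool(nta5),
    }
    active = [d for d, on in dims.items() if on]
    if not active:
        category = "canonical"
    elif len(active) > 1:
        category = "mixture"
    elif active == ["mismatch"]:
        category = "mismatch"
    elif active == ["indel"]:
        category = "insertion" if alignment.n_ins_bases else "deletion"
    elif active == ["shift"]:
        if shift5 != 0 and shift3 != 0:
            category = "mixture"
        elif shift5 != 0:
            category = "super5" if shift5 < 0 else "sub5"
        else:
            category = "super3" if shift3 > 0 else "sub3"
    else:  # nta
        category = "nta3" if nta3 else "nta5"
    return IsomiRRecord(
        read_uid=alignment.read_uid,
        mature_id=locus.mature_id,
        shift5=shift5,
        shift3=shift3,
        n_mismatch=alignment.n_mismatch,
        n_ins=alignment.n_ins_bases,
        n_del=alignment.n_del_bases,
        mismatch_detail=detail,
        nta3=nta3,
        nta5=nta5,
        nta_class=nta_class,
        adapter_remnant=remnant,
        a_to_g_only=a_to_g,
        category=category,
    )


def classify_library(
    qualified: Iterable[QualifiedMapping],
    read_seqs: Mapping[str, str],
    hairpin_seqs: Mapping[str, str],
    adapter: str | None = None,
) -> list[tuple[IsomiRRecord, Fraction]]:
    """Classify every qualified mapping of a library, keeping its count share."""
    out = []
    for q in qualified:
        rec = classify_read(
            read_seqs[q.read_uid], q.alignment, q.locus,
            hairpin_seqs[q.alignment.hairpin_id], q.shift5, q.shift3, adapter,
        )
        out.append((rec, q.share))
    return out


@dataclass
class IsomiRSummary:
    """Category, NTA-class and editing tabulation for one library.

    Fractions are over the counted mature-read total, weighted by collapsed
    read counts (each qualified mapping contributes its count share).
    """

    total: Fraction
    category_counts: dict[str, Fraction]
    category_fractions: dict[str, float]
    nta_counts: dict[str, Fraction]        # polyA / polyU / other, remnants excluded
    nta_fractions: dict[str, float]        # fractions of NTA-positive reads
    a_to_g_count: Fraction
    mismatch_only_count: Fraction
    a_to_g_fraction: float


def tabulate(records: Sequence[tuple[IsomiRRecord, Fraction]]) -> IsomiRSummary:
    """Tabulate weighted isomiR records into the library summary."""
    total = sum((w for _, w in records), Fraction(0))
    cat: dict[str, Fraction] = {c: Fraction(0) for c in CATEGORIES}
    nta: dict[str, Fraction] = {"polyA": Fraction(0), "polyU": Fraction(0), "other": Fraction(0)}
    a2g = Fraction(0)
    mismatch_only = Fraction(0)
    for rec, w in records:
        cat[rec.category] += w
        if rec.nta3 and not rec.adapter_remnant:
            nta[rec.nta_class] += w
        if rec.n_mismatch >= 1 and rec.n_ins == 0 and rec.n_del == 0:
            mismatch_only += w
            if rec.a_to_g_only:
                a2g += w
    nta_total = sum(nta.values(), Fraction(0))
    return IsomiRSummary(
        total=total,
        category_counts=cat,
        category_fractions={
            c: float(v / total) if total else 0.0 for c, v in cat.items()
        },
        nta_counts=nta,
        nta_fractions={
            c: float(v / nta_total) if nta_total else 0.0 for c, v in nta.items()
        },
        a_to_g_count=a2g,
        mismatch_only_count=mismatch_only,
        a_to_g_fraction=float(a2g / mismatch_only) if mismatch_only else 0.0,
    )
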