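"""Deterministic synthetic fixtures: hairpins, read libraries, genomes.

Everything the test surface needs is generated here under a seed, with a truth
manifest recording what was planted so downstream recovery can be checked
exactly.  Hairpins are built as perfect stem-loops (5' arm random, 3' arm its
reverse complement, random loop opening with a fixed C so that 3' tails on the
5p mature can never extend as template matches); mature miRNAs are excised
from each arm and named with the paired mature/hairpin convention
("syn-miR-<n>-5p" on "syn-mir-<n>").

Read libraries are drawn from a :class:`VariantProfile` whose category
fractions are realised as exact integer allocations (largest-remainder), so a
planted 60/25/15 composition is recovered as exactly 60/25/15 — the manifest
is the oracle, not an expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mirvar.formats import HairpinRecord, MatureRecord, SequenceRead, GenomeFeature, revcomp

BASES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_hairpin(
    seed: int, index: int = 1, arm_len: int = 22, loop_len: int = 12,
    species: str = "syn", bulges: int = 0,
) -> tuple[HairpinRecord, MatureRecord, MatureRecord]:
    """One stem-loop hairpin with planted 5p and 3p matures.

    hairpin = arm5 + loop + arm3 where arm3 is the reverse complement of the
    5' arm, optionally with ``bulges`` substitutions (imperfect stems, as real
    precursors have; also keeps a palindromic mature from mapping onto its own
    opposite arm on the minus strand).  mature5p = hairpin[0:arm_len];
    mature3p = the 3' arm.  The loop starts with 'C' so a non-C 3' tail
    appended to the 5p mature is always non-templated.
    """
    rng = np.random.default_rng((seed, index))
    arm5 = _random_seq(rng, arm_len)
    loop = "C" + _random_seq(rng, loop_len - 1)
    arm3 = list(revcomp(arm5))
    for pos in rng.choice(np.arange(2, arm_len - 2), size=bulges, replace=False):
        old = arm3[pos]
        arm3[pos] = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
    arm3_seq = "".join(arm3)
    hairpin_seq = arm5 + loop + arm3_seq
    hid = f"{species}-mir-{index}"
    hairpin = HairpinRecord(hid, hairpin_seq)
    mat5 = MatureRecord(f"{species}-miR-{index}-5p", arm5)
    mat3 = MatureRecord(f"{species}-miR-{index}-3p", arm3_seq)
    return hairpin, mat5, mat3


def make_reference(
    seed: int, n_hairpins: int = 3, arm_len: int = 22, loop_len: int = 12,
    species: str = "syn",
) -> tuple[list[HairpinRecord], list[MatureRecord]]:
    """A small miRBase-style reference set of hairpins and their matures."""
    hairpins, matures = [], []
    for idx in range(1, n_hairpins + 1):
        hp, m5, m3 = make_hairpin(seed, idx, arm_len, loop_len, species)
        hairpins.append(hp)
        matures.extend([m5, m3])
    return hairpins, matures


@dataclass(frozen=True)
class VariantProfile:
    """Planted isomiR composition of a synthetic library.

    Fractions must sum to 1; they are realised as exact integer counts.
    ``a_to_g_fraction`` is the sub-fraction of mismatch reads whose planted
    substitution is hairpin-A -> read-G.  ``fail_quality_fraction`` adds extra
    reads (on top of ``n_reads``) built to fail the Q20/95% rule.
    """

    canonical: float = 1.0
    super3: float = 0.0
    sub3: float = 0.0
    super5: float = 0.0
    sub5: float = 0.0
    mismatch: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    nta_polyA: float = 0.0
    nta_polyU: float = 0.0
    nta_other: float = 0.0
    mixture: float = 0.0
    a_to_g_fraction: float = 1.0
    n_reads: int = 1000
    fail_quality_fraction: float = 0.0
    seed: int = 0

    def fractions(self) -> dict[str, float]:
        return {
            "canonical": self.canonical, "super3": self.super3, "sub3": self.sub3,
            "super5": self.super5, "sub5": self.sub5, "mismatch": self.mismatch,
            "insertion": self.insertion, "deletion": self.deletion,
            "nta_polyA": self.nta_polyA, "nta_polyU": self.nta_polyU,
            "nta_other": self.nta_other, "mixture": self.mixture,
        }


def exact_allocation(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder integer allocation of ``n`` among ``fractions``."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {total}, expected 1")
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    deficit = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:deficit]:
        counts[k] += 1
    return counts


@dataclass
class TruthManifest:
    """What a synthetic library planted, keyed for downstream recovery tests.

    ``expected_category_counts`` are post-seed-check: planted 5' variants
    (super5/sub5) are filtered by the seed check and move to ``seed_filtered``.
    """

    n_reads: int
    planted_category_counts: dict[str, int]
    expected_category_counts: dict[str, int]
    expected_counts_per_mature: dict[str, int]
    nta_class_counts: dict[str, int]
    a_to_g_count: int
    mismatch_only_count: int
    seed_filtered: int
    failing_quality_ids: list[str]
    adapter: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


# map profile keys to the isomiR category the classifier should report
_EXPECTED_CATEGORY = {
    "canonical": "canonical", "super3": "super3", "sub3": "sub3",
    "super5": "super5", "sub5": "sub5", "mismatch": "mismatch",
    "insertion": "insertion", "deletion": "deletion",
    "nta_polyA": "nta3", "nta_polyU": "nta3", "nta_other": "nta3",
    "mixture": "mixture",
}


@lru_cache(maxsize=4096)
def _ungapped_best(read: str, hairpin: str, min_core: int = 15) -> int:
    """Minimum ungapped-with-free-clips penalty of ``read`` against ``hairpin``.

    Brute force over every clip pair and hairpin offset (mismatch penalty 30);
    used to certify that a planted indel read cannot be explained more cheaply
    without its gap.  Independent of the aligner.
    """
    m = len(read)
    best = 10**9
    for c5 in range(0, m - min_core + 1):
        for c3 in range(0, m - min_core - c5 + 1):
            core = read[c5 : m - c3]
            for off in range(0, len(hairpin) - len(core) + 1):
                mm = sum(1 for a, b in zip(core, hairpin[off:]) if a != b)
                best = min(best, 30 * mm)
                if best == 0:
                    return 0
    return best


def _build_variant(
    kind: str, hairpin: HairpinRecord, arm_len: int, loop_len: int,
    rng: np.random.Generator, gap_penalty: int = 46,
) -> tuple[str, str, str]:
    """One planted read of the given kind; returns (sequence, arm, actual kind).

    Error positions sit outside the seed window (read positions 2-8) so every
    planted kind except super5/sub5 survives the seed check, and far enough
    from the read 3' end that free soft-clipping cannot explain the variant
    more cheaply than its intended alignment (certified for indels with
    :func:`_ungapped_best`).  super5 reads come from the 3p arm (its upstream
    template is the loop); everything else from the 5p arm.  ``mismatch_a2g``
    falls back to a generic mismatch when the eligible window has no A, and
    the actual kind reports what was planted.
    """
    H = hairpin.sequence
    s5, e5 = 0, arm_len
    s3, e3 = arm_len + loop_len, len(H)
    k = int(rng.integers(1, 4))  # shift/tail length 1..3
    if kind == "canonical":
        return H[s5:e5], "5p", kind
    if kind == "super3":
        return H[s5 : e5 + k], "5p", kind
    if kind == "sub3":
        return H[s5 : e5 - k], "5p", kind
    if kind == "super5":
        return H[s3 - k : e3], "3p", kind
    if kind == "sub5":
        return H[s5 + k : e5], "5p", kind
    if kind in ("mismatch", "mismatch_a2g"):
        seq = list(H[s5:e5])
        # positions 9-15 (1-based): outside the seed, and close enough to the
        # 3' end that a clipped mismatch-free alignment cannot reach min_core
        lo, hi = 8, 15
        if kind == "mismatch_a2g":
            a_pos = [i for i in range(lo, hi) if seq[i] == "A"]
            if a_pos:
                pos = int(a_pos[int(rng.integers(0, len(a_pos)))])
                seq[pos] = "G"
                return "".join(seq), "5p", "mismatch_a2g"
            kind = "mismatch"
        pos = int(rng.integers(lo, hi))
        old = seq[pos]
        choices = [b for b in BASES if b != old and not (old == "A" and b == "G")]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
        return "".join(seq), "5p", "mismatch"
    if kind == "insertion":
        for _ in range(30):
            pos = int(rng.integers(9, 14))
            base_choices = [b for b in BASES if b != H[pos] and b != H[pos - 1]]
            base = base_choices[int(rng.integers(0, len(base_choices)))]
            seq = H[s5:pos] + base + H[pos:e5]
            if _ungapped_best(seq, H) > gap_penalty:
                return seq, "5p", kind
        raise RuntimeError(f"could not plant an unambiguous insertion in {hairpin.hairpin_id}")
    if kind == "deletion":
        for _ in range(30):
            pos = int(rng.integers(9, 14))
            seq = H[s5:pos] + H[pos + 1 : e5]
            if _ungapped_best(seq, H) > gap_penalty:
                return seq, "5p", kind
        raise RuntimeError(f"could not plant an unambiguous deletion in {hairpin.hairpin_id}")
    if kind == "nta_polyA":
        return H[s5:e5] + "A" * k, "5p", kind
    if kind == "nta_polyU":
        return H[s5:e5] + "T" * k, "5p", kind
    if kind == "nta_other":
        # tail must not begin with the templated loop base 'C' nor be a homopolymer
        tail = "G" + "T" * max(1, k - 1)
        return H[s5:e5] + tail, "5p", kind
    if kind == "mixture":
        # 3' super shift plus a non-templated 2-nt tail: two active dimensions;
        # the tail's first base avoids the next templated loop base so the
        # tail is clipped whole, and mixes bases so its NTA class is 'other'
        first = "G" if H[e5 + 1] != "G" else "T"
        tail = first + "A"
        return H[s5 : e5 + 1] + tail, "5p", kind
    raise ValueError(f"unknown variant kind {kind!r}")


def make_library(
    hairpins: Sequence[HairpinRecord],
    profile: VariantProfile,
    adapter: str | None = None,
    arm_len: int = 22,
    loop_len: int = 12,
    adapter_error_fraction: float = 0.0,
) -> tuple[list[SequenceRead], TruthManifest]:
    """A synthetic FASTQ library with planted isomiR composition.

    Reads are distributed round-robin over hairpins within each category.
    Every read gets Q40 bases; ``fail_quality_fraction`` adds reads with
    enough Q10 bases to fail the Q20/95% filter.  When ``adapter`` is given it
    is appended to every read (a planted single error in a fraction of them),
    so the library exercises trimming; the manifest records planted truth for
    the trimmed, collapsed, quantified library.
    """
    rng = np.random.default_rng(profile.seed)
    alloc = exact_allocation(profile.fractions(), profile.n_reads)
    if alloc.get("mismatch"):
        n_a2g = int(round(profile.a_to_g_fraction * alloc["mismatch"]))
    else:
        n_a2g = 0
    reads: list[SequenceRead] = []
    planted: dict[str, int] = {}
    expected: dict[str, int] = {}
    per_mature: dict[str, int] = {}
    nta_counts = {"polyA": 0, "polyU": 0, "other": 0}
    a2g_count = 0
    mismatch_only = 0
    seed_filtered = 0
    seq_category: dict[str, str] = {}
    serial = 0

    def add_read(seq: str, qualities: tuple[int, ...] | None = None, rid: str | None = None) -> str:
        nonlocal serial
        serial += 1
        rid = rid or f"r{serial}"
        full = seq
        quals = qualities if qualities is not None else (40,) * len(seq)
        if adapter is not None:
            ad = adapter
            if adapter_error_fraction and rng.random() < adapter_error_fraction:
                pos = int(rng.integers(0, len(ad)))
                repl = BASES[(BASES.index(ad[pos]) + 1) % 4] if ad[pos] in BASES else "A"
                ad = ad[:pos] + repl + ad[pos + 1 :]
            full = seq + ad
            quals = tuple(quals) + (40,) * len(ad)
        reads.append(SequenceRead(rid, full, tuple(quals)))
        return rid

    hp_cycle = 0
    for kind in sorted(alloc):
        n_kind = alloc[kind]
        for i in range(n_kind):
            hp = hairpins[hp_cycle % len(hairpins)]
            hp_cycle += 1
            species_stem = hp.hairpin_id.rsplit("-", 1)
            build_kind = kind
            if kind == "mismatch" and i < n_a2g:
                build_kind = "mismatch_a2g"
            seq, arm, actual = _build_variant(build_kind, hp, arm_len, loop_len, rng)
            prev = seq_category.get(seq)
            label = _EXPECTED_CATEGORY[kind]
            if prev is not None and prev != label:
                raise RuntimeError(
                    f"fixture collision: sequence planted as both {prev} and {label}"
                )
            seq_category[seq] = label
            add_read(seq)
            planted[label] = planted.get(label, 0) + 1
            mature_id = f"{species_stem[0]}-{species_stem[1]}-{arm}".replace("-mir-", "-miR-")
            if kind in ("super5", "sub5"):
                seed_filtered += 1
                continue
            expected[label] = expected.get(label, 0) + 1
            per_mature[mature_id] = per_mature.get(mature_id, 0) + 1
            if kind == "nta_polyA":
                nta_counts["polyA"] += 1
            elif kind == "nta_polyU":
                nta_counts["polyU"] += 1
            elif kind in ("nta_other", "mixture"):
                # mixture reads carry a mixed-base 3' tail classified 'other'
                nta_counts["other"] += 1
            if kind == "mismatch":
                mismatch_only += 1
                if actual == "mismatch_a2g":
                    a2g_count += 1
    failing_ids: list[str] = []
    n_fail = int(round(profile.fail_quality_fraction * profile.n_reads))
    for _ in range(n_fail):
        hp = hairpins[hp_cycle % len(hairpins)]
        hp_cycle += 1
        seq = hp.sequence[:arm_len]
        n_low = int(np.ceil(0.05 * len(seq))) + 1
        quals = [40] * len(seq)
        for j in range(n_low):
            quals[j] = 10
        failing_ids.append(add_read(seq, tuple(quals)))
    manifest = TruthManifest(
        n_reads=profile.n_reads,
        planted_category_counts=planted,
        expected_category_counts=expected,
        expected_counts_per_mature=per_mature,
        nta_class_counts=nta_counts,
        a_to_g_count=a2g_count,
        mismatch_only_count=mismatch_only,
        seed_filtered=seed_filtered,
        failing_quality_ids=failing_ids,
        adapter=adapter,
    )
    return reads, manifest


def make_arm_libraries(
    hairpins: Sequence[HairpinRecord],
    design: Mapping[str, str],
    plan: Mapping[str, Mapping[str, str]],
    arm_len: int = 22,
    loop_len: int = 12,
    dominant_count: int = 50,
    minor_count: int = 10,
    none_counts: tuple[int, int] = (30, 20),
) -> tuple[dict[str, list[SequenceRead]], dict[str, dict[str, dict[str, int]]]]:
    """Canonical-read libraries with planted per-treatment arm dominance.

    ``plan`` maps hairpin id -> {treatment: '5p' | '3p' | 'none'}; hairpins
    absent from the plan get 'none' everywhere.  Default counts satisfy the
    dominance criteria (50 vs 10: fold 5 > 2, diff 40 > 10) and the 'none'
    pair fails them (30 vs 20: fold 1.5).  Returns ({library: reads},
    {library: {hairpin: {'5p': n, '3p': n}}}).
    """
    libraries: dict[str, list[SequenceRead]] = {}
    truth: dict[str, dict[str, dict[str, int]]] = {}
    for lib, treat in sorted(design.items()):
        reads: list[SequenceRead] = []
        lib_truth: dict[str, dict[str, int]] = {}
        serial = 0
        for hp in hairpins:
            form = plan.get(hp.hairpin_id, {}).get(treat, "none")
            seq5 = hp.sequence[:arm_len]
            seq3 = hp.sequence[arm_len + loop_len :]
            if form == "5p":
                n5, n3 = dominant_count, minor_count
            elif form == "3p":
                n5, n3 = minor_count, dominant_count
            else:
                n5, n3 = none_counts
            for seq, n in ((seq5, n5), (seq3, n3)):
                for _ in range(n):
                    serial += 1
                    reads.append(SequenceRead(f"{lib}-r{serial}", seq, (40,) * len(seq)))
            lib_truth[hp.hairpin_id] = {"5p": n5, "3p": n3}
        libraries[lib] = reads
        truth[lib] = lib_truth
    return libraries, truth


@dataclass
class GenomeFixture:
    """A synthetic genome with planted hairpin, decoy genes, and layout truth."""

    genome: dict[str, str]
    features: list[GenomeFeature]
    hairpin_spans: dict[str, tuple[str, int, int]]
    decoy_spans: dict[str, tuple[str, int, int, str]]  # gene_id -> (chrom, start, end, biotype)


def make_genome(
    hairpins: Sequence[HairpinRecord],
    seed: int = 0,
    spacer_len: int = 200,
    decoys: Sequence[tuple[str, str, int]] = (("gene_pc1", "protein_coding", 300), ("gene_rrna1", "rRNA", 150)),
) -> GenomeFixture:
    """Embed hairpins and decoy genes in one random chromosome.

    Layout: spacer, hairpin1, spacer, ..., then each decoy gene followed by a
    spacer.  Features carry biotype 'miRNA' for hairpins and the decoy's
    biotype for decoys; coordinates in the returned spans are the oracle for
    catalog and novel-prediction tests.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    pos = 0
    features: list[GenomeFeature] = []
    hairpin_spans: dict[str, tuple[str, int, int]] = {}
    decoy_spans: dict[str, tuple[str, int, int, str]] = {}
    chrom = "chr1"

    def push(seq: str) -> int:
        nonlocal pos
        start = pos
        parts.append(seq)
        pos += len(seq)
        return start

    push(_random_seq(rng, spacer_len))
    for hp in hairpins:
        start = push(hp.sequence)
        hairpin_spans[hp.hairpin_id] = (chrom, start, start + len(hp.sequence))
        features.append(
            GenomeFeature(chrom, start, start + len(hp.sequence), "+", hp.hairpin_id, "miRNA")
        )
        push(_random_seq(rng, spacer_len))
    for gene_id, biotype, length in decoys:
        seq = _random_seq(rng, length)
        start = push(seq)
        decoy_spans[gene_id] = (chrom, start, start + length, biotype)
        features.append(GenomeFeature(chrom, start, start + length, "+", gene_id, biotype))
        push(_random_seq(rng, spacer_len))
    return GenomeFixture(
        genome={chrom: "".join(parts)},
        features=features,
        hairpin_spans=hairpin_spans,
        decoy_spans=decoy_spans,
    )


def make_novel_reads(
    fixture: GenomeFixture,
    hairpin: HairpinRecord,
    arm_len: int = 22,
    major_count: int = 30,
    minor_count: int = 5,
    minor_offset: int = 4,
) -> tuple[list[SequenceRead], str]:
    """Reads supporting a planted novel hairpin: one dominant arm stack.

    ``major_count`` copies of the 5p mature plus ``minor_count`` copies of a
    template read shifted ``minor_offset`` nt downstream; the two piles
    overlap, so they merge into one genome stack whose top signature stack is
    the planted mature (30 > 2 x 5).  Returns (reads, planted mature
    sequence).
    """
    chrom, start, _end = fixture.hairpin_spans[hairpin.hairpin_id]
    genome_seq = fixture.genome[chrom]
    mature = genome_seq[start : start + arm_len]
    shifted = genome_seq[start + minor_offset : start + minor_offset + arm_len]
    reads = [
        SequenceRead(f"novel-r{i}", mature, (40,) * len(mature)) for i in range(major_count)
    ] + [
        SequenceRead(f"novel-s{i}", shifted, (40,) * len(shifted)) for i in range(minor_count)
    ]
    return reads, mature


def write_genome_sam(
    path: str | Path,
    fixture: GenomeFixture,
    records: Sequence[tuple[str, str | None, int | None, int, str]],
) -> None:
    """Write planted genome alignments as SAM.

    ``records`` are (read uid, chrom or None for unmapped, 0-based start,
    aligned length, strand).  Sequences are written as '*'.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in fixture.genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for uid, chrom, start, length, strand in records:
            if chrom is None:
                fh.write(f"{uid}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
            else:
                flag = 16 if strand == "-" else 0
                fh.write(
                    f"{uid}\t{flag}\t{chrom}\t{start + 1}\t60\t{length}M\t*\t0\t0\t*\t*\n"
                )
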