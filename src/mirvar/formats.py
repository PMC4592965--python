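"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; the converters in this module are
the only places where offsets change (GTF 1-based inclusive -> half-open, SAM POS
1-based -> 0-based).  The internal alphabet is DNA: U is converted to T on input
and sequences are uppercased; writers that emit RNA (novel precursor FASTA/DBN)
convert back on output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read with Sanger (offset-33) Phred scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA (hairpin) reference sequence, DNA alphabet."""

    hairpin_id: str
    sequence: str


@dataclass(frozen=True)
class MatureRecord:
    """A canonical mature miRNA reference sequence, DNA alphabet."""

    mature_id: str
    sequence: str


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    biotype: str


@dataclass(frozen=True)
class GenomeAlignment:
    """A genome alignment record as carried by SAM.

    ``ops`` is a run-length operation list of (op, length) tuples with op in
    {'M', 'I', 'D', 'S'}; it consumes exactly the read length.  ``mapped`` is
    False for unmapped records, which carry no coordinates.
    """

    read_uid: str
    chrom: str | None
    start: int | None
    ops: tuple[tuple[str, int], ...]
    strand: str
    mapping_quality: int
    mapped: bool = True
    sequence: str = ""

    @property
    def end(self) -> int | None:
        """End on the reference (half-open), from reference-consuming ops."""
        if not self.mapped:
            return None
        return self.start + sum(n for op, n in self.ops if op in ("M", "D"))


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream 4-line FASTQ records as :class:`SequenceRead`.

    Sequences are uppercased with U->T.  Raises :class:`ParseError` naming the
    1-based line number of the first malformed record.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield SequenceRead(
                read_id=header[1:].split()[0] if len(header) > 1 else "",
                sequence=seq.upper().replace("U", "T"),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(path: str | Path, reads: Iterable[SequenceRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from FASTA; U->T, uppercased.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids raise :class:`ParseError`.
    """
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        yield rec.id, str(rec.seq).upper().replace("U", "T")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], *, rna: bool = False,
                descriptions: dict[str, str] | None = None) -> None:
    """Write (id, sequence) records as FASTA; ``rna=True`` converts T->U on write."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for rec_id, seq in records:
            desc = descriptions.get(rec_id, "")
            header = f">{rec_id} {desc}".rstrip()
            fh.write(f"{header}\n{to_rna(seq) if rna else seq}\n")


def read_hairpins(path: str | Path) -> list[HairpinRecord]:
    records = [HairpinRecord(i, s) for i, s in read_fasta(path)]
    for rec in records:
        if not rec.sequence:
            raise ParseError(f"{path}: empty hairpin sequence for {rec.hairpin_id}")
    return records


def read_matures(path: str | Path) -> list[MatureRecord]:
    records = [MatureRecord(i, s) for i, s in read_fasta(path)]
    for rec in records:
        if len(rec.sequence) < 15:
            logger.warning("mature %s is shorter than 15 nt", rec.mature_id)
    return records


def parse_mifam(path: str | Path) -> dict[str, list[str]]:
    """Parse a miFam.dat-style family file into {family_name: [precursor ids]}.

    Stanzas carry AC/ID header lines and MI member lines and are terminated by
    '//'.  Members are recorded under both their accession and their name so
    either keying works downstream.
    """
    families: dict[str, list[str]] = {}
    seen_members: dict[str, str] = {}
    family_name = None
    members: list[str] = []
    open_stanza = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "AC":
                open_stanza = True
            elif tag == "ID":
                open_stanza = True
                family_name = line[2:].strip()
            elif tag == "MI":
                open_stanza = True
                # MI line: accession then precursor name
                parts = line[2:].split()
                for token in parts:
                    members.append(token)
            elif line.startswith("//"):
                if family_name is None:
                    raise ParseError(f"{path}: line {lineno}: stanza without ID line")
                for m in members:
                    if m in seen_members and seen_members[m] != family_name:
                        raise ParseError(
                            f"{path}: precursor {m!r} appears in families "
                            f"{seen_members[m]!r} and {family_name!r}"
                        )
                    seen_members[m] = family_name
                families.setdefault(family_name, []).extend(
                    m for m in members if m not in families.get(family_name, ())
                )
                family_name, members, open_stanza = None, [], False
    if open_stanza:
        raise ParseError(f"{path}: unterminated stanza (missing '//')")
    return families


def family_of(families: dict[str, list[str]]) -> dict[str, str]:
    """Invert a family table to {precursor id or name: family name}."""
    out: dict[str, str] = {}
    for fam, members in families.items():
        for m in members:
            out[m] = fam
    return out


def parse_gtf(path: str | Path, feature_kind: str = "exon") -> Iterator[GenomeFeature]:
    """Stream features of one kind from a GTF file as 0-based half-open intervals.

    gene_id comes from the attribute column; the biotype is taken from the
    'gene_biotype' attribute, falling back to 'biotype', then to the source
    column (Ensembl dialect).  Lines without gene_id are skipped with a warning.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None, keep_order=True)
            if feat.featuretype != feature_kind:
                continue
            gene_id = feat.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                logger.warning("%s: line %d: no gene_id attribute; skipped", path, lineno)
                continue
            biotype = (
                feat.attributes.get("gene_biotype", [None])[0]
                or feat.attributes.get("biotype", [None])[0]
                or feat.source
            )
            yield GenomeFeature(
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                gene_id=gene_id,
                biotype=biotype,
            )


_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def read_sam(path: str | Path) -> Iterator[GenomeAlignment]:
    """Stream SAM records as :class:`GenomeAlignment` (POS converted to 0-based).

    Unmapped records (flag 0x4) are yielded with ``mapped=False`` and no
    coordinates.  CIGAR N/H/P ops are not supported for short-read input and
    raise :class:`ParseError`.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                yield GenomeAlignment(
                    read_uid=rec.query_name, chrom=None, start=None, ops=(),
                    strand=".", mapping_quality=rec.mapping_quality, mapped=False,
                    sequence=(rec.query_sequence or ""),
                )
                continue
            ops = []
            for code, length in rec.cigartuples or ():
                if code not in _CIGAR_OPS:
                    raise ParseError(
                        f"{path}: unsupported CIGAR op code {code} in read {rec.query_name}"
                    )
                ops.append((_CIGAR_OPS[code], length))
            yield GenomeAlignment(
                read_uid=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                ops=tuple(ops),
                strand="-" if rec.is_reverse else "+",
                mapping_quality=rec.mapping_quality,
                sequence=(rec.query_sequence or ""),
            )


def write_dbn(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, dot_bracket) triples in DBN format.

    The structure must be the same length as the sequence and have balanced
    parentheses.  Sequences are written as RNA.
    """
    with open(path, "w") as fh:
        for rec_id, seq, structure in records:
            if len(structure) != len(seq):
                raise ValueError(
                    f"{rec_id}: structure length {len(structure)} != sequence length {len(seq)}"
                )
            depth = 0
            for ch in structure:
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                    if depth < 0:
                        raise ValueError(f"{rec_id}: unbalanced dot-bracket structure")
                elif ch != ".":
                    raise ValueError(f"{rec_id}: invalid structure character {ch!r}")
            if depth != 0:
                raise ValueError(f"{rec_id}: unbalanced dot-bracket structure")
            fh.write(f">{rec_id}\n{to_rna(seq)}\n{structure}\n")


def write_counts_csv(path: str | Path, table: dict[str, dict[str, int]],
                     libraries: list[str] | None = None, id_column: str = "id") -> None:
    """Write an id x library integer count table as CSV.

    ``table`` maps row id -> {library: count}.  Row order is the insertion
    order of ``table``; column order is ``libraries`` when given, otherwise
    sorted library names.
    """
    if libraries is None:
        libs: list[str] = sorted({lib for row in table.values() for lib in row})
    else:
        libs = list(libraries)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([id_column] + libs)
        for row_id, row in table.items():
            writer.writerow([row_id] + [row.get(lib, 0) for lib in libs])


def read_counts_csv(path: str | Path) -> tuple[dict[str, dict[str, int]], list[str]]:
    """Read a count CSV written by :func:`write_counts_csv`; returns (table, libraries)."""
    table: dict[str, dict[str, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        libs = header[1:]
        for row in reader:
            table[row[0]] = {lib: int(v) for lib, v in zip(libs, row[1:])}
    return table, libs
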