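"""Union-mode cataloging of genome-aligned reads by annotated feature.

Counting mirrors htseq-count's "union" resolution at its defaults: the gene
set for a read is every gene_id whose features overlap any aligned base; an
empty set is 'no_feature', more than one gene is 'ambiguous', and multi-mapped
reads are resolved by their primary alignment only.  Counting is unstranded by
default.  Buckets partition the library: every read lands in exactly one of a
gene, no_feature, ambiguous, below_quality, or unmapped, so bucket totals
conserve the clean-read count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from mirvar.formats import GenomeAlignment, GenomeFeature

SPECIAL_BUCKETS = ("no_feature", "ambiguous", "unmapped", "below_quality")


@dataclass
class CatalogTable:
    """Per-biotype read counts plus special buckets for one library."""

    biotype_counts: dict[str, int]
    special: dict[str, int]
    total: int

    def fractions(self) -> dict[str, float]:
        """Percent denominators are total clean reads, not mapped reads."""
        if self.total == 0:
            return {}
        out = {b: c / self.total for b, c in self.biotype_counts.items()}
        out.update({b: c / self.total for b, c in self.special.items()})
        return out


def _aligned_blocks(aln: GenomeAlignment) -> list[tuple[int, int]]:
    """Reference intervals covered by aligned read bases (M ops only)."""
    blocks = []
    pos = aln.start
    for op, n in aln.ops:
        if op == "M":
            blocks.append((pos, pos + n))
            pos += n
        elif op == "D":
            pos += n
    return blocks


def count_features(
    alignments: Iterable[GenomeAlignment],
    features: Sequence[GenomeFeature],
    min_quality: int = 0,
    stranded: bool = False,
    weights: Mapping[str, int] | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Union-mode per-gene counts plus special buckets.

    ``weights`` optionally expands collapsed reads by their support counts
    (keyed by read uid; unknown uids weigh 1).  Secondary alignments of a uid
    already counted are ignored (primary alignment only).
    """
    trees: dict[str, IntervalTree] = {}
    strands: dict[tuple[str, int, int, str], set[str]] = {}
    for feat in features:
        trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end, feat)
    gene_counts: Counter[str] = Counter()
    special = Counter({b: 0 for b in SPECIAL_BUCKETS})
    seen: set[str] = set()
    for aln in alignments:
        if aln.read_uid in seen:
            continue
        seen.add(aln.read_uid)
        w = (weights or {}).get(aln.read_uid, 1)
        if not aln.mapped:
            special["unmapped"] += w
            continue
        if aln.mapping_quality < min_quality:
            special["below_quality"] += w
            continue
        genes: set[str] = set()
        tree = trees.get(aln.chrom)
        if tree is not None:
            for lo, hi in _aligned_blocks(aln):
                for iv in tree.overlap(lo, hi):
                    feat: GenomeFeature = iv.data
                    if stranded and feat.strand != aln.strand:
                        continue
                    genes.add(feat.gene_id)
        if not genes:
            special["no_feature"] += w
        elif len(genes) > 1:
            special["ambiguous"] += w
        else:
            gene_counts[genes.pop()] += w
    return dict(gene_counts), dict(special)


def aggregate_biotypes(
    gene_counts: Mapping[str, int],
    special: Mapping[str, int],
    features: Sequence[GenomeFeature],
) -> CatalogTable:
    """Sum per-gene counts by biotype into the catalog table."""
    biotype_of: dict[str, str] = {}
    for feat in features:
        biotype_of.setdefault(feat.gene_id, feat.biotype)
    by_biotype: Counter[str] = Counter()
    for gene_id, count in gene_counts.items():
        by_biotype[biotype_of.get(gene_id, "unknown")] += count
    total = sum(gene_counts.values()) + sum(special.values())
    return CatalogTable(
        biotype_counts=dict(by_biotype), special=dict(special), total=total
    )
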