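"""End-to-end pipeline over one or more FASTQ libraries.

Stages run in order: quality filter -> adapter trim -> collapse -> hairpin
mapping -> quantification (matures, families) -> isomiR classification, with
optional novel prediction and genome cataloging.  Each stage logs input/kept
tallies; all CSV outputs are deterministic (byte-identical across reruns with
the same config and inputs).  Arm switching is a separate entry point run on
the finished count table (see :mod:`mirvar.armswitch`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from mirvar import formats
from mirvar.formats import read_fastq, read_hairpins, read_matures, parse_mifam, write_counts_csv
from mirvar.hairpin_align import AlignParams, locate_matures, map_all
from mirvar.isomir import classify_library, tabulate, CATEGORIES
from mirvar.preprocess import TrimSettings, collapse, detect_adapter, quality_filter, trim_library
from mirvar.quantify import QuantSettings, QuantTable, assign_counts, family_counts, round_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage executes)."""


@dataclass
class RunConfig:
    libraries: dict[str, str]          # library name -> FASTQ path
    hairpin_fasta: str
    mature_fasta: str
    mifam: str | None = None
    output_dir: str = "mirvar_out"
    trim: TrimSettings = field(default_factory=TrimSettings)
    align: AlignParams = field(default_factory=AlignParams)
    quant: QuantSettings = field(default_factory=QuantSettings)
    min_quality: int = 20
    min_quality_fraction: float = 0.95
    auto_detect_adapter: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.libraries:
            raise ConfigError("no input libraries")
        for name, path in self.libraries.items():
            if not Path(path).exists():
                raise ConfigError(f"library {name!r}: missing FASTQ {path}")
        for label, path in (("hairpin", self.hairpin_fasta), ("mature", self.mature_fasta)):
            if not Path(path).exists():
                raise ConfigError(f"missing {label} reference file {path}")
        if self.mifam is not None and not Path(self.mifam).exists():
            raise ConfigError(f"missing family file {self.mifam}")


@dataclass
class LibraryResult:
    name: str
    stage_stats: dict[str, dict[str, int]]
    mapping_stats: dict[str, int]
    quant_tallies: dict[str, int]
    isomir_summary: object


@dataclass
class PipelineResult:
    output_dir: Path
    table: QuantTable
    family_table: dict[str, dict[str, Fraction]]
    libraries: dict[str, LibraryResult]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage for every configured library and write outputs."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    hairpins = read_hairpins(config.hairpin_fasta)
    matures = read_matures(config.mature_fasta)
    loci = locate_matures(matures, hairpins)
    hairpin_seqs = {hp.hairpin_id: hp.sequence for hp in hairpins}
    families = parse_mifam(config.mifam) if config.mifam else {}
    mature_to_hairpin = {l.mature_id: l.hairpin_id for l in loci}

    table = QuantTable()
    lib_results: dict[str, LibraryResult] = {}
    lib_order = list(config.libraries)
    for name in lib_order:
        path = config.libraries[name]
        logger.info("library %s: reading %s", name, path)
        raw = list(read_fastq(path))
        kept, n_dropped = quality_filter(raw, config.min_quality, config.min_quality_fraction)
        logger.info(
            "library %s: quality filter kept %d/%d (%.2f%%)",
            name, len(kept), len(raw), 100 * len(kept) / len(raw) if raw else 0.0,
        )
        trim = config.trim
        if config.auto_detect_adapter and not trim.skip_trimming and trim.adapter is None:
            detected = detect_adapter(kept)
            if detected is not None:
                logger.info(
                    "library %s: detected adapter %s (%.1f%% of reads)",
                    name, detected[0], 100 * detected[1],
                )
                trim = TrimSettings(
                    adapter=detected[0], max_errors=trim.max_errors,
                    min_adapter_len=trim.min_adapter_len, min_read_len=trim.min_read_len,
                )
            else:
                logger.info("library %s: no adapter detected", name)
        clean, trim_stats = trim_library(kept, trim)
        clean = [r for r in clean if len(r) >= trim.min_read_len]
        logger.info(
            "library %s: trimming kept %d reads (%s)", name, len(clean), trim_stats
        )
        collapsed = collapse(clean)
        logger.info("library %s: %d collapsed reads", name, len(collapsed))
        mappings, map_stats = map_all(collapsed, hairpins, config.align)
        quant = assign_counts(collapsed, mappings, loci, hairpin_seqs, config.quant)
        table.add_library(name, quant)
        read_seqs = {c.uid: c.sequence for c in collapsed}
        iso_records = classify_library(quant.qualified, read_seqs, hairpin_seqs, trim.adapter)
        summary = tabulate(iso_records)
        _write_isomir_csvs(outdir, name, iso_records, summary)
        lib_results[name] = LibraryResult(
            name=name,
            stage_stats={
                "quality": {"input": len(raw), "kept": len(kept), "dropped": n_dropped},
                "trim": trim_stats,
                "collapse": {"clean": len(clean), "collapsed": len(collapsed)},
            },
            mapping_stats=map_stats,
            quant_tallies=quant.tallies,
            isomir_summary=summary,
        )

    write_counts_csv(outdir / "mature_counts.csv", table.rounded(), lib_order, "mature_id")
    fam = family_counts(table, families, mature_to_hairpin)
    write_counts_csv(outdir / "family_counts.csv", round_table(fam), lib_order, "family")
    return PipelineResult(
        output_dir=outdir, table=table, family_table=fam, libraries=lib_results
    )


def _write_isomir_csvs(outdir: Path, name: str, records, summary) -> None:
    import csv

    with open(outdir / f"isomir_{name}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["read_uid", "mature_id", "category", "shift5", "shift3",
             "n_mismatch", "n_ins", "n_del", "nta3", "nta_class",
             "adapter_remnant", "a_to_g_only", "weight"]
        )
        for rec, w in records:
            writer.writerow(
                [rec.read_uid, rec.mature_id, rec.category, rec.shift5, rec.shift3,
                 rec.n_mismatch, rec.n_ins, rec.n_del, rec.nta3, rec.nta_class,
                 int(rec.adapter_remnant), int(rec.a_to_g_only), float(w)]
            )
    with open(outdir / f"isomir_summary_{name}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "count", "fraction"])
        for cat in CATEGORIES:
            writer.writerow(
                [cat, float(summary.category_counts[cat]), summary.category_fractions[cat]]
            )
        for cls in ("polyA", "polyU", "other"):
            writer.writerow(
                [f"nta_{cls}", float(summary.nta_counts[cls]), summary.nta_fractions[cls]]
            )
        writer.writerow(["a_to_g_only", float(summary.a_to_g_count), summary.a_to_g_fraction])
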