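# mirvar

Quantification and variation analysis of microRNAs from small-RNA sequencing
reads.

Small-RNA libraries are dominated by ~22-nt mature miRNAs excised from the 5′
(5p) or 3′ (3p) arm of ~70–100 nt stem-loop precursors (pre-miRNA hairpins).
Sequenced copies of a miRNA are rarely uniform: imprecise precursor cleavage
shifts their ends, RNA editing (A→I, read out as A→G) changes internal bases,
and untemplated adenylation/uridylation appends 3′ tails.  These isomiRs, and
flips of the dominant arm between conditions ("arm switching"), are
biologically meaningful but are flattened or miscounted by tools that forbid
indels and soft clips in mapping or that add a multi-mapping read's full count
to every hairpin it hits.

`mirvar` is for researchers who want count tables *and* the variation detail:
it takes FASTQ libraries plus a miRBase-style reference (hairpin FASTA, mature
FASTA, optional `miFam.dat` family table) and produces mature-miRNA and family
count tables ready for DESeq2, per-read isomiR classifications, arm-switch
calls across treatments, novel pre-miRNA candidates excised from genome read
stacks, and genome-annotation read catalogs.

## The method

**Mapping.** Collapsed clean reads (distinct sequences with support counts)
are aligned to every hairpin by a penalty-capped semi-global dynamic program:
mismatch = 30, a gap of length *L* costs 40 + 6·*L*, terminal soft clips are
free, and alignments with penalty > 60 are discarded — so an alignment carries
at most 2 mismatches or one gap of ≤ 3 nt.  All alignments tied at a read's
minimum penalty are kept.

**Quantification.** A read is counted for a canonical mature when its aligned
core ends within ±3 nt of the annotated mature ends (*position check*) and,
optionally, when read positions 2–8 reproduce the canonical seed exactly, with
no 5′ clip or 5′ shift (*seed check*).  A multi-mapping read keeps only its
qualified mappings with the fewest soft-clipped bases and its count *c* is
divided evenly over those *k* mappings (each receives *c/k*, kept as an exact
rational), so ∑ counts equals the number of counted reads — no over-counting.
Family counts sum the matures of each precursor family; orphans form singleton
families.

**Variation.** Each counted read is classified along four dimensions — end
shifts (super/sub at 5′/3′), internal mismatches (with a pure-A→G editing
flag), indels, and 3′ non-templated addition (the 3′ soft-clipped bases,
classified poly(A)/poly(U)/other, with adapter-remnant screening) — into one
category, or `mixture` when several apply.  Arm switching calls a hairpin
whose dominant arm (count fold-change > 2 **and** difference > 10 between
arms, replicate-consistent) differs between treatments.

## Worked example

Everything runs on synthetic data generated by the built-in fixture module —
no downloads:

```sh
mirvar fixtures --seed 7 --out fx --n-reads 1000 --adapter ATCTCGTATGCCGTCTTCTGCTTG
mirvar quantify fx/library.fastq \
    --mature fx/mature.fa --hairpin fx/hairpin.fa \
    --adapter ATCTCGTATGCCGTCTTCTGCTTG --out out
```

The fixture plants 1000 reads over three hairpins with a known composition
(55% canonical, 20% 3′-super, 5% 3′-sub, 5% mismatch, 13% 3′-tailed,
2% mixture).  The run prints the per-stage tallies

```
library: {'total': 1000, 'mapped': 1000, 'passed_position': 1000,
          'passed_seed': 1000, 'counted': 1000, 'multi_mapped': 0, ...}
```

meaning every clean read mapped, passed both checks and was counted, and
writes `out/mature_counts.csv`:

```
mature_id,library
syn-miR-1-5p,334
syn-miR-1-3p,0
syn-miR-2-5p,333
...
```

— the 1000 counted reads split 334/333/333 over the three planted 5p matures
(all variants were planted on the 5p arm), matching `fx/manifest.json`
exactly.  `out/isomir_summary_library.csv` recovers the planted composition:

```
category,count,fraction
canonical,550.0,0.55
mismatch,50.0,0.05
...
```

Arm switching runs afterwards on the finished count table:

```sh
mirvar armswitch --counts out/mature_counts.csv --design design.tsv \
    --mature fx/mature.fa --hairpin fx/hairpin.fa --out switches.csv
```

where `design.tsv` maps each library to its treatment (one `library<TAB>treatment`
line per library; at least two treatments are required).

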