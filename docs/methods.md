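# Methods

## Alignment model

Reads are aligned to hairpins sense-strand only (mature reads are sense to
their precursors) with an affine-gap, penalty-minimizing semi-global dynamic
program.  Defaults: mismatch 30; gap open 40; gap extension 6 per gapped base
(a gap of length *L* costs 40 + 6·*L*); total penalty cap 60; terminal soft
clips on the read are free.  The arithmetic of these defaults means a
reportable alignment contains either at most two mismatches (2 × 30 = 60) or
exactly one gap of at most three bases (40 + 18 = 58 ≤ 60 < 64); a gap plus a
mismatch (≥ 76) or two gaps (≥ 92) are never reportable.  The DP is
nevertheless written for arbitrary penalties: each cell keeps, per reachable
cost ≤ cap, the longest aligned core achievable, which is cheap because the
set of admissible costs is tiny.

Because clips are free, a minimum-core constraint (default 15 nt, the minimum
clean-read length) prevents degenerate mostly-clipped alignments.  Clips are
canonical: a terminal read base adjacent to the core is clipped only when
aligning it would cost a mismatch or run past the hairpin end, so a
full-length match is reported once rather than alongside all its equal-cost
clipped sub-alignments.  All alignments tied at a read's global minimum
penalty are enumerated (deduplicated by locus and operations; reads with more
than 200 tied optima are truncated with a warning).  `N` never matches
anything — it always costs the mismatch penalty — and N counts are tracked
separately in the alignment record.

The test suite checks the DP against an independent brute-force oracle that
enumerates alignment families directly from run-length structure (sliding
mismatch windows per diagonal; clean prefix/suffix run pairs for single gaps)
on 500 random read/hairpin pairs.

## Quantification

Canonical mature loci are found by exact substring search of each mature in
its id-paired hairpin (`xxx-miR-7-5p` pairs with `xxx-mir-7`); the arm label
comes from the -5p/-3p suffix, or from the locus midpoint's hairpin half when
no suffix exists.  The position check passes a mapping when both end shifts of
its aligned core (clips excluded) relative to a locus are ≤ 3 nt; among
passing loci the minimal total shift wins, ties to the 5p arm.  The seed check
additionally requires no 5′ clip, a 5′ shift of exactly zero, and read
positions 2–8 aligned as uninterrupted matches.  Shifts are measured on the
aligned core, excluding clipped bases, which are by construction not part of
the mapped span.

Counts are assigned per collapsed read: no qualified mapping → discarded
(tallied by failure stage); one → full count; several → only the mappings with
the fewest total soft-clipped bases (best priority) retain the read, and its
count is divided evenly among them as exact rationals (`fractions.Fraction`),
so column sums equal counted-read totals with no float drift.  A read tied
between two loci on one hairpin is treated like any multi-mapping, which keeps
the conservation identity exact.  Rounding to integers for CSV output is
half-away-from-zero.  Family aggregation assigns each precursor's matures to
its family from the miFam-style table; matures of unfamilied precursors form
singleton families named by the mature id, so family totals partition mature
totals.

## IsomiR classification

Each counted read varies (or not) along four dimensions relative to its
canonical mature: end shifts, mismatches, indels, and non-templated 3′
addition.  The 3′ tail is read off as the 3′ soft-clipped bases of the optimal
alignment — clipped bases either disagree with the following hairpin bases or
run past the hairpin end, so they are non-templated by construction of the
optimum.  Exactly one active dimension gives that category (shift at both ends
counts as two shift calls, hence `mixture`); several give `mixture`.  Tails
are classed poly(A) / poly(U) / other (DNA space, so U is detected as T and
reported with RNA vocabulary); tails of ≥ 5 nt matching an adapter prefix
within one edit are flagged as possible adapter remnants, stay counted, but
are excluded from the tail-class sub-table.  A read is an editing candidate
(`a_to_g_only`) when it has ≥ 1 mismatch, no indels, and every mismatch is
hairpin-A/read-G; the editing fraction is reported over mismatch-only reads.
5′ clips are recorded (`nta5`) but with the seed check on such reads are
filtered before classification, so tables report zero 5′ variants.  Category
fractions are weighted by read counts (each qualified mapping contributes its
count share), matching per-read percentage semantics.

## Arm switching

For hairpins with exactly one annotated mature per arm, an arm dominates a
library when fold-change > 2 and difference > 10 (both strict; with a zero
denominator the fold criterion is satisfied by any positive numerator).  A
treatment's form is defined only when all its replicates agree on the same
non-none arm; a switch is called when ≥ 2 treatments have defined forms that
differ.  Raw integer counts are compared, as the criteria are count-scale
thresholds; users comparing libraries of very different depths should be aware
the difference threshold is depth-sensitive.

## Novel precursor prediction

Perfect (exact substring, both strands) genome mappings of collapsed reads
with mapped lengths 18–25 nt and ≤ 5 loci are merged into read stacks by
coordinate overlap.  Each stack is excised in two orientations — 10 nt flank
on the mature side and 70 nt on the loop side, both configurable — and
collapsed reads plus known matures are re-mapped perfectly onto each candidate
as its signature (no mismatches, to cut false positives).  The top signature
stack's sequence becomes the candidate's mature only when its read count
strictly exceeds twice the second stack's (a lone positive stack is accepted);
candidates with no such dominant stack are discarded, and the first surviving
orientation per stack wins.  Secondary-structure folding and hairpin scoring
are delegated to a pluggable backend returning `(dot_bracket, score)`:
candidates scoring ≤ 0 are dropped, a structure in which the mature base-pairs
with itself is rejected, and without a backend candidates pass through marked
`unscored`.  Names unify across libraries by genomic coordinates
(`<species>-novel-mir-<n>` in genomic sort order, matures suffixed a/b/… when
one precursor yields several sequences), novel matures are annotated with a
known mature sharing their exact seed (positions 2–8) when one exists, and
novel quantification re-runs the standard pipeline against the novel
precursors with perfect mappings only.

## Read cataloging

Genome alignments (SAM) are tallied against GTF features in union mode at its
defaults: the gene set for a read is every `gene_id` overlapping any aligned
base; none → `no_feature`, several → `ambiguous`; primary alignments only;
minimum mapping quality 0; unstranded by default with a strict-strand option.
Gene counts aggregate by `gene_biotype` (falling back to `biotype`, then the
GTF source column).  Buckets partition the library, and reported percentages
use total clean reads as the denominator, not mapped reads.

## Adapter handling

Quality filtering keeps a read when ≥ 95% of its bases have Phred ≥ 20
(boundary inclusive).  Adapter occurrences are adapter prefixes of ≥ 10 nt
matched with ≤ 1 unit-cost edit, either a full adapter found internally or a
prefix reaching the read's 3′ end; occurrences may not begin with an inserted
read base.  Among qualifying occurrences the fewest errors wins, then the
leftmost start: preferring fewer errors keeps a chance agreement between the
insert's last base and the adapter's first base from shaving a base off the
insert when an exact occurrence follows.  When the planted error sits in the
adapter's first two bases that ambiguity is information-theoretic — both
parses are equally consistent — and the trim point may land one base into the
insert; the tests exercise this case separately.  Inserts shorter than 15 nt
after trimming are dropped.  Empirical adapter detection seeds on the most
frequent 10-mer in the 3′ halves of sampled reads (floor: 20% of reads) and
extends it in both directions by ≥ 80% base consensus.

## Synthetic data generator

Fixtures are fully deterministic under a seed.  Hairpins are perfect
stem-loops (5′ arm random, 3′ arm its reverse complement, optionally with
`bulges` substitutions for imperfect stems — also needed so a palindromic
mature does not map onto its own opposite arm on the minus strand), with the
loop opening fixed to `C` so a non-C tail on the 5p mature can never extend as
template.  Library composition is realised by largest-remainder integer
allocation, so planted fractions are exact and the manifest is an oracle, not
an expectation.  Planted error positions sit outside the seed window and far
enough from read ends that free soft-clipping cannot explain them more
cheaply; indel plantings are certified by an independent ungapped-with-clips
brute force and re-drawn if ambiguous.  What the generator does *not* emulate:
position-dependent sequencing error profiles, expression-level biology,
quality-score structure (all-Q40 bases apart from planted failures), genome
repeat structure, or multi-chromosome genomes — so passing tests demonstrate
algorithmic correctness on controlled compositions, not performance on real
libraries.

Default study conditions used by the tests: 3 hairpins (22 nt arms, 12 nt
loops); libraries of 400 reads for unit-level recovery and 10⁴ reads for the
at-scale recovery check; arm-switch libraries plant 50 vs 10 reads for a
dominant arm (fold 5, diff 40) and 30 vs 20 for no dominance; the novel-locus
fixture plants a 30-read mature stack plus 5 overlapping shifted reads.

## Acceptance fixture

`scripts/acceptance.py` probes the penalty model's admissibility boundaries on
a 70-nt random hairpin derived from the run seed.  Substitutions are planted
at central read positions (8–13 of a 22-mer) so clipping cannot excise them
while keeping the 15-nt core, and deletion sites are screened with the
independent ungapped brute force so no clip-only alignment undercuts the
planted gap; sub-seeds are re-drawn until those certifications hold.  The
reported values are whatever the aligner actually admits.

## Known limitations

- Hairpin mapping is all-vs-all DP, intended for references of short hairpin
  sets, not genome-scale indexing.
- Genome mapping for novel prediction is exact substring search; supplying an
  external aligner's SAM is supported for cataloging but large-genome
  alignment is out of scope.
- Base qualities do not influence alignment scores.
- miRDeep2-style probabilistic scoring, randfold randomization tests and MFE
  computation are deliberately external (the scoring backend interface), not
  re-implemented.
- Differential expression is out of scope; the count tables are integer,
  library-per-column CSVs intended as DESeq2 input.
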