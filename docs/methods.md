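# Methods

## Problem and model

RNA proximity-ligation protocols (RIC-seq and psoralen-based methods
such as PARIS, LIGR-seq, SPLASH) religate spatially close RNA strands,
so a sequenced fragment can align with two distinct split types: a
canonical GT/AG splice split and a non-canonical ligation split. A
single-split aligner must trade intron accuracy against contact
sensitivity. The two-pass strategy resolves this upstream of this
package: splice junctions are learned from a ligation-free control
RNA-seq experiment on a first alignment pass and supplied to the second
pass as bona fide introns. `proxilig` implements everything downstream
of the second-pass aligner: split classification, ligation-point
clustering, contact assembly and export.

### Split classification

Co-linear splits (same chromosome, same strand, forward orientation)
appear as `N` operations in the SAM CIGAR; non-co-linear splits appear
in the aligner's chimeric-junction table because a single CIGAR cannot
represent them. A co-linear split whose skipped interval matches the
*known splice set* — the union of control-derived and
annotation-derived introns — is discarded as splicing; the rest are
**neo-junctions**. Chimeric rows are kept as **chimeric junctions**;
rows with junction type −1 (the junction falls between unsequenced read
mates, so there is no defined ligation point) are excluded by default,
appropriate when the second pass is aligned single-end. Same-chromosome
backward-orientation chimeras are retained: they encode intragenic
contacts, as in circular RNAs.

Matching against the known set is exact by default (`tolerance: 0`),
following the convention of comparing junctions by exact genomic
position; a symmetric ±t nt tolerance on both intron edges is available.
Strand is recorded but ignored for junction identity: religation strand
assignment is protocol-ambiguous. Multi-mapped reads (mapping quality
below the unique-mapper value, default 255) are excluded from junction
extraction by default.

Every junction is reduced to two **ligation points**: the last aligned
base before and the first aligned base after the skipped region. For
chimeric rows the breakpoint columns are strand-directed (first/last
skipped base along the donor/acceptor strand); the point is recovered by
stepping one base back toward the aligned segment, which makes neo and
chimeric points directly comparable.

### Clustering

Gap-placement variability between alignments of the same ligation point
and the stochasticity of digestion/religation smear ligation points over
a few nucleotides, so points are clustered rather than matched exactly.
Per chromosome, sorted points are grouped by single linkage with cutoff
δ: consecutive points join one cluster iff their distance is **≤ δ**
(the inclusive reading of "minimum distance between two points in a
cluster"; a linear sweep over sorted points is exactly single linkage in
one dimension, and the test suite checks it against an O(n²)
transitive-closure oracle). Supported cutoffs are δ = 10 nt (default)
and δ = 20 nt. Clusters are exported 0-based half-open as
[min − ⌊δ/2⌋, max + ⌊δ/2⌋), so an isolated point yields a cluster of
length δ for even δ. The left flank is clipped at coordinate 0, the one
place where a cluster may be shorter than δ; chromosome-end clipping on
the right is not applied because cluster construction does not know
chromosome sizes.

### Contacts

A contact is an unordered pair of clusters linked by at least one
ligation junction, canonically ordered by (chromosome, start). Read
support r counts **distinct read ids** across linking junctions — a
read supporting two junctions between the same cluster pair counts once,
which guards against double counting re-parsed alignments, and is
equivalent to summing junction read counts whenever read ids are unique
per junction. Junctions whose two points fall in the same cluster are
dropped as self-contacts and reported separately, since a contact is by
definition a pair of clusters. Categories: **intragenic** iff both
cluster intervals overlap at least one common annotated gene; **cis**
iff same chromosome and not intragenic (a pair with only one genic end
on the same chromosome is cis under this literal reading); **trans**
otherwise. Distance d is the absolute difference of cluster midpoints,
floored at 1 nt so log₂ d stays defined for overlapping clusters;
midpoints are the natural reference once junction-level coordinates have
been replaced by clusters.

Per-category statistics report n, mean ± sd of cluster length s (each
contact contributes both of its clusters), log₂ d (intragenic/cis only)
and log₂ r, with the n − 1 denominator; a category with fewer than two
values reports an undefined (blank) sd, and an empty category reports
n = 0.

### Tracks and matrices

The BED12 arc track keeps same-chromosome contacts whose outer span
(downstream cluster end − upstream cluster start) is at most 50,000 nt
(inclusive; default, configurable), with the two cluster intervals as
blocks and score = min(1000, r). Orientation is deliberately ignored for
"co-linear" here; categories already encode topology. Contact matrices
are binned by cluster midpoint at 100-bp resolution (default) into
upper-triangle (i ≤ j) COO triplets written as plain text — conversion
to a cooler container is a documented one-liner rather than a
dependency. Binned mass equals the summed read support of the binned
contacts (a tested invariant).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta` | 10 nt | single-linkage cutoff; 20 nt is the supported alternative |
| `tolerance` | 0 nt | splice-junction matching tolerance (exact) |
| `unique_only` / `unique_mapq` | true / 255 | exclude reads below the unique-mapper quality |
| `include_mate_encompassing` | false | keep junction-type −1 chimeric rows |
| `max_span` | 50,000 nt | co-linear track span cutoff (inclusive) |
| `bin_size` | 100 bp | contact-matrix resolution |

## Synthetic fixtures

The generator (`proxilig.simulate`) emits already-aligned second-pass
outputs — SAM text, control and annotation splice-junction tables, a
chimeric table, a gene GTF — plus truth tables. It plants: splice-only
reads over every intron; co-linear neo-junctions, half intragenic (a
subset carried on reads that also traverse an annotated intron, the
mixed splice + ligation read structure characteristic of these assays)
and half cis across genes; chimeras, half trans and half same-chromosome
backward-orientation (intragenic); multi-mapped decoy reads and unmapped
reads. A subset of introns is omitted from the annotation table so the
two-pass specificity property is testable: excluding with the annotation
alone makes exactly those introns reappear as spurious ligation
junctions.

Default conditions: two 1-Mb chromosomes, 6 genes of 20 kb, 2 introns
per gene (3 of 12 unannotated), 12 neo + 12 chimeric planted junctions
(24 contacts), 3 reads per junction, per-read coordinate jitter ±2 nt,
read length 75 nt, 40 splice reads, 2 multi-mapped and 2 unmapped reads
— a desk-scale genome whose every planted ligation point is ≥ 150 nt
from any other. That separation exceeds 2δ + 2·jitter for both supported
cutoffs, which makes recovery exactly decidable: each planted junction
maps to one recovered contact and precision = recall = 1 is the expected
outcome, not a tolerance. All randomness flows from one mandatory seed;
fixtures are byte-reproducible.

What the fixtures do **not** emulate: sequence content and alignment
errors (reads are emitted as alignments, so aligner-side effects such as
soft-clip rescue, gap-placement ambiguity beyond uniform jitter, or the
ligation-site micro-insertion are upstream concerns), PCR duplication
(read support counts distinct read ids with no positional
deduplication), expression-level variation, and realistic genome/gene
density. Passing tests therefore demonstrate correctness of the
parsing, exclusion, clustering and contact logic under controlled
conditions — not end-to-end accuracy on real libraries, which depends
on the upstream aligner.

## Numerical and design notes

- Classification and clustering are deterministic and order-independent;
  the pipeline contains no unseeded randomness, and stage manifests
  record input/output checksums so identical runs are byte-identical.
- CIGAR parsing accepts all SAM operations; splits are reported one per
  `N` operation, with `D` consuming reference but never reported as a
  split.
- Tie-break at the cutoff: a gap of exactly δ merges.
- Degenerate inputs: empty junction sets yield empty (but valid)
  outputs; a mapped-only alignment stream cannot determine the mapped
  fraction, so the mapping summary takes an optional total read count
  and otherwise reports 0 with a warning; fewer than two ligation points
  per chromosome yields an empty distance-quantile table with a warning.
- Statistical significance of contacts is intentionally out of scope:
  read support in individual proximity-ligation libraries is sparse
  (most cis/trans contacts carry one read), and a background model is a
  separate problem.

## Known limitations

- Gene-level categorization uses gene spans, not exon structure; a
  contact inside an intron of a gene still counts as genic.
- Chimeric parsing consumes breakpoint columns only; segment CIGARs are
  carried but not re-walked, so sub-segment splice splits inside
  chimeric reads are not re-classified.
- BED12 records collapse overlapping cluster blocks into one block to
  remain format-valid, losing the block boundary in that rare case.
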