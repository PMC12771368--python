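# Methods

## The reconstruction model

A sequenced full-length cDNA read carries, in one molecule, the three
determinants of a transcript isoform: where transcription started, which
introns were spliced out, and where the transcript was cleaved and
polyadenylated.  `isopeak` treats each uniquely mapped long read as one
piece of evidence for the triple (TSS, intron chain, PA) and reconstructs
isoforms as read groups that agree on all three.  Two assumptions underlie
this: reads are **orientation-unified** (already flipped into mRNA sense by
upstream processing, so a `+` alignment has its 5′ end at the alignment
start and a `-` alignment at the end), and biological replicates are
available (≥ 2), because replicate concordance is the primary noise filter
at both the position level and the isoform level.

Internally every coordinate is 0-based half-open; GTF and STAR
`SJ.out.tab` conventions (1-based inclusive) are applied exactly once, at
the format boundary.

## Stages and parameters

**Read quality and poly(A).**  A read passes when its whole-read quality is
at least `quality_min` (default 7), computed as −10·log₁₀ of the *mean
per-base error probability* — the read-level pass/fail convention of
nanopore basecallers.  Per-base trimming at such a low threshold would
shred long reads, so the threshold is interpreted read-wise.  Poly(A)
tails are removed with 3′-adapter semantics for an A₁₀₀ adapter: the
best-scoring run of A's ending at (or overhanging) the 3′ end with
mismatch rate ≤ `polya_error_rate` (0.1) and overlap ≥ 3 is cut together
with everything 3′ of it; trimming iterates to a fixed point so the
operation is idempotent.

**Alignment and the unique-alignment filter.**  Alignment is a contract
wrapper around an external splice-aware aligner (default arguments
`-ax splice -k14 -uf -G 10k`); user-supplied SAM/BAM bypasses it.  A read
is kept only if it produced exactly one alignment record counting primary
and supplementary records together, and no secondaries.  This removes both
multi-mappers and chimeric (split) reads, an artifact class long-read cDNA
protocols are known to produce.  The stricter reading of "single
alignment" — dropping primary+supplementary pairs — was chosen because
chimeras are precisely the motivating artifact.

**Splice correction.**  Candidate introns are the `N` operations of the
CIGAR.  The junction reference keeps introns seen in
≥ `junction_min_samples` (2) distinct samples (duplicates within one
sample count once); an annotation used as a junction source counts as a
single always-passing sample.  Correction is per gap, independently: among
reference introns with both |Δdonor| ≤ 10 bp and |Δacceptor| ≤ 10 bp *of
the same intron*, the minimal total displacement wins (ties: smaller
donor, then smaller acceptor); an unmatched gap is removed (treated as a
deletion).  Per-intron rather than per-boundary matching was chosen
because replacement substitutes one reference intron as a unit; matching
is coordinate-only by default (strand-aware matching is a config toggle)
and strand-undefined junctions match reads of either strand.  A corrected
chain is re-checked for order and overlap; a replacement overlapping its
neighbour is dropped with a warning.

**Downsampling (optional).**  Highly expressed genes produce many reads
from tattered RNA whose 5′ ends blanket the gene body and distort TSS
detection.  With an annotation, each read is attributed to the single gene
it overlaps most (ties: larger overlap fraction of the read, then
lexicographic gene id — single attribution keeps the cap meaningful for
overlapping genes); genes with more than `downsample_cap` (1000) attributed
reads keep exactly 1000 chosen uniformly, and genes under `min_gene_reads`
(5) are ignored.  Without an annotation, per-strand per-base coverage is
computed and, within each maximal run of positions above the cap, reads
covering the current maximum-coverage position are removed one at a time
until the run is at the cap.  Each (replicate, chromosome, strand) scope
draws from its own generator derived from the global seed by stable
hashing, so results are reproducible regardless of execution order.

**End peaks.**  Each read contributes exactly one 5′ and one 3′ position
to four tracks per chromosome (2 strands × 2 end types), kept per
replicate.  A position enters the pooled track only when nonzero in
≥ `support_min_replicates` (2) replicates; pooled counts are plain sums
(no TPM or depth normalisation).  Candidate positions with pooled count
strictly greater than `pooled_cutoff` (2) are clustered left to right:
consecutive candidates merge when separated by fewer than `merge_dist_bp`
(10) non-candidate positions (100 and 110 merge, 100 and 111 do not).
The strict cutoff comparison and the gap convention are declared in the
config docs because an off-by-one here changes every peak; summit ties
break to the transcription-direction 5′-most candidate for determinism.

**Isoforms and genes.**  Reads whose 5′ end falls in no TSS region or
whose 3′ end falls in no PA region are excluded (with reason codes, and
conservation — assigned + rejected = input — is asserted in tests).
Groups keyed by (TSS peak, exact chain, PA peak) are kept when the largest
per-replicate count is ≥ `high_count` (5) and the second largest
≥ `low_count` (1) — provably equivalent to "≥ 5 in one replicate and ≥ 1
in a different one".  The isoform span runs between the outer bounds of
its two peak regions; spans overlapping by ≥ `gene_overlap_frac` (0.8) of
the shorter span are linked, and genes are the connected components
(union-find) of that relation, strand-separately (merging antisense
overlap would contradict stranded peak calling).  Genes are named from an
annotation by the same 80% rule (largest absolute overlap wins, same
strand only); otherwise they get stable coordinate-derived ids
(`IPKG_<chrom>_<start>_<strand>`), with isoforms suffixed `.i<k>` by
descending count.  The optional minor filter keeps a non-major isoform
only when its summed count strictly exceeds `minor_frac` (0.01) of the
major's.  Emitted exon structures use the peak *summits* as terminal
coordinates — FASTA output requires a point, and the summit is the
region's point representation; the rare isoform whose summits are
inconsistent with its chain is dropped with a warning.

## The simulator

The simulator emulates the features of real long-read cDNA data that the
pipeline's filters are built to handle: multi-isoform genes with
alternative TSS/PA (inward offsets of ≥ 25 bp so distinct ends remain
separable) and shared or distinct intron chains with canonical GT..AG
boundaries; negative-binomial expression (n = 1, p = 0.004, mean ≈ 249
reads per isoform per replicate, or fixed overrides); 5′/3′ truncation
from an end-completeness mixture — full length with probability 0.85,
otherwise Beta(2, 1), mean 0.95, reflecting the upstream filtering that
keeps only cDNAs with adapters at both ends; integer-Gaussian end jitter
(sd 3 bp, clamped inside the transcript); substitutions (2%) and indels
(1%); poly(A) tails (15–60 nt); and optional splice-gap wobble that slides
whole junctions by up to 3 bp in the emitted alignments to emulate aligner
imprecision near gaps.  Every read's error-free genomic alignment is
emitted as a truth SAM so all downstream stages can be exercised without
an external aligner; the FASTQ output carries the error-injected sequence
for end-to-end runs through a real aligner.

What it does **not** emulate: the full error profile of any particular
basecaller (homopolymer bias, quality-correlated errors), internal
poly(A) priming, genomic DNA contamination, expression differences
between replicates, and overlapping or nested genes.  Passing tests on
this generator therefore demonstrate the correctness of the algorithmic
contracts and robustness to end/splice noise at desk scale — not
performance on any particular real library.

The annotation distorter shifts transcript boundaries by 100 bp in one of
seven equiprobable ways (5′ or 3′ or both ends, upstream or downstream in
transcription direction, or no change), moving terminal exons only and
stopping 1 bp short of the first/last splice junction.

## Evaluation

Points mode scores a prediction as correct only when its 5′ point, intron
chain and 3′ point are identical to an etalon transcript on the same
chromosome and strand; matching is greedy in prediction order, each etalon
matches at most once, and duplicates are false positives (the true-positive
count is order-invariant).  Peaks mode requires the identical chain with
the etalon terminal points contained in the predicted 5′/3′ regions.
Point-based predictions from other tools are expanded to ±N/2 around each
point, where N is the reference gene's maximal end-peak length (one N per
gene, the larger of the 5′ and 3′ maxima) and gene correspondence uses
> 10% span intersection; predictions matching no gene fall back to
halfwidth 0.  When predictions carry per-replicate counts, only those
detected in ≥ 2 replicates are scored.  Peak sets from two methods are
compared per peak as intersecting (with intersection rate = overlapped
fraction of the query peak), proximal (nearest edge ≤ 10 bp) or
unsupported.

## Numerical and degenerate-input choices

Ties everywhere break deterministically (documented per stage above), all
collections are iterated in sorted order, and per-scope RNG streams are
derived by CRC32 hashing of the scope labels, so identically seeded runs
are byte-identical.  Empty inputs return empty outputs (empty alignment
files, empty tracks, empty junction tables); malformed CIGAR strings,
quality/sequence length mismatches, unreadable alignment files, isoforms
with zero exons, missing chromosomes in the genome, and fewer replicates
than the support threshold are fatal errors.  Desk-scale problem sizes are
used throughout the tests and the acceptance script (20-gene toy genomes,
30–50 reads per isoform per replicate), which reconstructs in seconds on
one CPU.

## Known limitations

- Reads must be orientation-unified upstream; the pipeline does not infer
  strand from poly(A) position or splice motifs.
- No realignment or motif (GT-AG) scoring around junctions; correction is
  purely coordinate-based against the reference set.
- Quantification is raw supporting-read counts; no length or depth
  normalisation, no ORF prediction, no splicing-event classification.
- Single-exon isoforms are grouped by end peaks alone and are therefore
  more sensitive to end-jitter than spliced ones.
- The gene model is a span-overlap cluster; nested or overlapping
  same-strand genes will merge when their isoform spans satisfy the 80%
  rule.
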