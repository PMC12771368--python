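"""Synthetic data generation for pipeline validation.

Generates toy genomes with multi-isoform genes (alternative TSS/PA and
shared or distinct intron chains), simulates long cDNA reads with 5'/3'
truncation, end jitter, substitution/indel errors and poly(A) tails, and can
distort an annotation by shifting transcript boundaries.  Besides FASTQ, the
simulator emits the error-free genomic alignment of every read as a truth
SAM so downstream stages can be exercised without an external aligner.

The defaults mirror a long-read cDNA experiment at desk scale: negative
binomial expression with n=1, p=0.004 (mean ~249 reads per isoform), mean
end completeness 0.95, end jitter with sd 3 bp, 2% substitutions and 1%
indels, three biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .intervals import GenomicInterval
from .io import (AnnotationTranscript, isoform_sequence, reverse_complement,
                 write_annotation_gtf, write_genome_fasta)

log = logging.getLogger(__name__)

DISTORTION_CASES = (
    "none",
    "five_downstream", "five_upstream",
    "three_downstream", "three_upstream",
    "both_upstream", "both_downstream",
)


@dataclass
class SimConfig:
    """Parameters of the toy-genome and read simulator.

    ``completeness_5p``/``completeness_3p`` describe the fraction of the
    transcript retained when truncating from the respective end: a float is
    a constant, an ``(a, b)`` tuple draws from Beta(a, b), and a
    ``(p_full, a, b)`` triple is a mixture — full length with probability
    ``p_full``, else Beta(a, b) — which is the shape of empirical long-read
    end-completeness profiles (a point mass at 1 plus a truncation tail).
    ``expression_nb``
    is the (n, p) of the negative-binomial read count per isoform per
    replicate; ``reads_per_isoform`` (an int, or a mapping transcript_id ->
    int) overrides it with fixed counts.
    """

    n_chroms: int = 2
    chrom_len: int = 100_000
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (1, 4)
    exons_per_isoform: tuple[int, int] = (1, 5)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (60, 300)
    expression_nb: tuple[float, float] = (1.0, 0.004)
    reads_per_isoform: int | Mapping[str, int] | None = None
    # 85% of reads full length (the upstream read filtering keeps only cDNAs
    # with adapters at both ends), the rest truncated ~ Beta(2, 1); mean 0.95
    completeness_5p: float | tuple = (0.85, 2.0, 1.0)
    completeness_3p: float | tuple = (0.85, 2.0, 1.0)
    end_jitter_sd: float = 3.0
    subst_rate: float = 0.02
    indel_rate: float = 0.01
    polya_len: tuple[int, int] = (15, 60)
    n_replicates: int = 3
    min_read_len: int = 30
    splice_jitter_prob: float = 0.0
    splice_jitter_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subst_rate", "indel_rate", "splice_jitter_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("isoforms_per_gene", "exons_per_isoform", "exon_len",
                     "intron_len", "polya_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range {lo}..{hi} is empty")


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

# inward 5'/3' offsets available to alternative TSS/PA variants; spaced so
# that distinct end peaks never merge at the default merge distance (10 bp)
_ALT_OFFSETS = (25, 50, 75)
_GENE_MARGIN = 500


def make_toy_genome(sim: SimConfig
                    ) -> tuple[dict[str, str], list[AnnotationTranscript]]:
    """Random toy genome plus its truth annotation.

    Genes are placed without overlap on alternating strands; each gene's
    isoforms share the backbone intron chain and differ by alternative TSS,
    alternative PA, and/or retained introns.  Canonical GT..AG dinucleotides
    are written at every intron boundary (CT..AC on the genomic plus strand
    for minus-strand genes).
    """
    rng = np.random.default_rng(sim.seed)
    chrom_names = [f"chr{i + 1}" for i in range(sim.n_chroms)]
    chroms = {name: rng.choice(list("ACGT"), size=sim.chrom_len)
              for name in chrom_names}
    cursors = {name: _GENE_MARGIN for name in chrom_names}
    transcripts: list[AnnotationTranscript] = []

    for g in range(sim.n_genes):
        chrom = chrom_names[g % sim.n_chroms]
        strand = "+" if (g // sim.n_chroms) % 2 == 0 else "-"
        n_exons = int(rng.integers(sim.exons_per_isoform[0],
                                   sim.exons_per_isoform[1] + 1))
        exon_lens = rng.integers(sim.exon_len[0], sim.exon_len[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(sim.intron_len[0], sim.intron_len[1] + 1,
                                   size=max(0, n_exons - 1))
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom] + int(rng.integers(200, 800))
        if start + gene_len + _GENE_MARGIN > sim.chrom_len:
            raise ValueError(
                f"gene {g} does not fit on {chrom} "
                f"(need {start + gene_len + _GENE_MARGIN} > {sim.chrom_len} bp); "
                "increase chrom_len or reduce n_genes")
        cursors[chrom] = start + gene_len

        exons, introns = [], []
        pos = start
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + int(elen)))
            pos += int(elen)
            if i < len(intron_lens):
                introns.append((pos, pos + int(intron_lens[i])))
                pos += int(intron_lens[i])
        for s, e in introns:
            donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
            chroms[chrom][s:s + 2] = list(donor)
            chroms[chrom][e - 2:e] = list(acceptor)

        gene_id = f"G{g:04d}"
        k = int(rng.integers(sim.isoforms_per_gene[0],
                             sim.isoforms_per_gene[1] + 1))
        variants = _gene_variants(rng, k, n_exons, strand, exons)
        for v, (d5, d3, dropped) in enumerate(variants, 1):
            tx_exons = _variant_exons(exons, introns, strand, d5, d3, dropped)
            loc = GenomicInterval(chrom, tx_exons[0][0], tx_exons[-1][1], strand)
            transcripts.append(AnnotationTranscript(
                f"{gene_id}.t{v}", gene_id, loc,
                [GenomicInterval(chrom, s, e, strand) for s, e in tx_exons]))
    genome = {name: "".join(seq) for name, seq in chroms.items()}
    return genome, transcripts


def _gene_variants(rng: np.random.Generator, k: int, n_exons: int,
                   strand: str, exons: list[tuple[int, int]]
                   ) -> list[tuple[int, int, frozenset]]:
    """k distinct (5' offset, 3' offset, dropped introns) variants.

    Offsets shortening the terminal exons must leave them >= 25 bp so that
    the variant transcript stays well-formed.
    """
    variants = [(0, 0, frozenset())]
    first_len = exons[0][1] - exons[0][0]
    last_len = exons[-1][1] - exons[-1][0]
    attempts = 0
    while len(variants) < k and attempts < 200:
        attempts += 1
        d5 = int(rng.choice((0,) + _ALT_OFFSETS))
        d3 = int(rng.choice((0,) + _ALT_OFFSETS))
        dropped = frozenset()
        if n_exons > 1 and rng.random() < 0.4:
            dropped = frozenset({int(rng.integers(n_exons - 1))})
        left_off, right_off = (d5, d3) if strand == "+" else (d3, d5)
        if n_exons == 1:
            if left_off + right_off > first_len - 25:
                continue
        elif left_off > first_len - 25 or right_off > last_len - 25:
            continue
        cand = (d5, d3, dropped)
        if cand not in variants:
            variants.append(cand)
    return variants


def _variant_exons(exons: list[tuple[int, int]], introns: list[tuple[int, int]],
                   strand: str, d5: int, d3: int, dropped: frozenset
                   ) -> list[tuple[int, int]]:
    """Apply variant modifications to the backbone exon chain."""
    merged: list[tuple[int, int]] = []
    for i, exon in enumerate(exons):
        if merged and (i - 1) in dropped:        # retained intron: merge
            merged[-1] = (merged[-1][0], exon[1])
        else:
            merged.append(exon)
    left_off, right_off = (d5, d3) if strand == "+" else (d3, d5)
    first = (merged[0][0] + left_off, merged[0][1])
    last = (merged[-1][0], merged[-1][1] - right_off)
    if len(merged) == 1:
        return [(first[0], last[1])]
    return [first] + merged[1:-1] + [last]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    read_id: str
    transcript_id: str
    replicate: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]        # genomic alignment blocks, sorted
    clean_seq: str                       # mRNA-sense sequence, error-free
    fastq_seq: str                       # with errors and poly(A) tail


@dataclass
class SimulatedData:
    genome: dict[str, str]
    transcripts: list[AnnotationTranscript]
    reads_by_replicate: dict[str, list[SimulatedRead]] = field(default_factory=dict)


def _draw_completeness(rng: np.random.Generator, spec: float | tuple) -> float:
    if isinstance(spec, tuple):
        if len(spec) == 3:
            p_full, a, b = spec
            return 1.0 if rng.random() < p_full else float(rng.beta(a, b))
        return float(rng.beta(*spec))
    return float(spec)


def simulate_reads(genome: dict[str, str],
                   transcripts: Sequence[AnnotationTranscript],
                   sim: SimConfig) -> SimulatedData:
    """Simulate reads for every isoform in every replicate.

    Per isoform per replicate the read count is negative binomial (or the
    fixed override); each read is the transcript sequence truncated by the
    completeness draws, its ends jittered inward/outward (clamped to the
    transcript), with substitutions and indels injected and a poly(A) tail
    appended.  The error-free genomic alignment (exon blocks) is recorded
    alongside; optional splice wobble slides whole junctions by up to
    ``splice_jitter_max`` bp to emulate aligner imprecision near gaps.
    """
    data = SimulatedData(genome=dict(genome), transcripts=list(transcripts))
    for r in range(sim.n_replicates):
        rep = f"rep{r + 1}"
        rng = np.random.default_rng((sim.seed * 1000003 + 7919 * (r + 1))
                                    % (2 ** 31))
        reads: list[SimulatedRead] = []
        for tx in transcripts:
            n_reads = _read_count(rng, sim, tx.transcript_id)
            tx_seq = isoform_sequence(tx, genome)
            for i in range(n_reads):
                read = _one_read(rng, sim, tx, tx_seq, rep, i)
                if read is not None:
                    reads.append(read)
        data.reads_by_replicate[rep] = reads
        log.info("simulated %d reads for %s", len(reads), rep)
    return data


def _read_count(rng: np.random.Generator, sim: SimConfig, tx_id: str) -> int:
    if sim.reads_per_isoform is None:
        n, p = sim.expression_nb
        return int(rng.negative_binomial(n, p))
    if isinstance(sim.reads_per_isoform, Mapping):
        return int(sim.reads_per_isoform[tx_id])
    return int(sim.reads_per_isoform)


def _one_read(rng: np.random.Generator, sim: SimConfig,
              tx: AnnotationTranscript, tx_seq: str, rep: str,
              serial: int) -> SimulatedRead | None:
    L = len(tx_seq)
    start_t = round(L * (1.0 - _draw_completeness(rng, sim.completeness_5p)))
    end_t = L - round(L * (1.0 - _draw_completeness(rng, sim.completeness_3p)))
    if sim.end_jitter_sd > 0:
        start_t += round(rng.normal(0.0, sim.end_jitter_sd))
        end_t += round(rng.normal(0.0, sim.end_jitter_sd))
    start_t = max(0, min(start_t, L - 1))
    end_t = max(start_t + 1, min(end_t, L))
    if end_t - start_t < sim.min_read_len:
        start_t = max(0, end_t - sim.min_read_len)
        if end_t - start_t < sim.min_read_len:
            return None
    blocks = _transcript_slice_blocks(tx, start_t, end_t)
    if sim.splice_jitter_prob > 0:
        blocks = _wobble_junctions(rng, blocks, sim.splice_jitter_prob,
                                   sim.splice_jitter_max)
    clean = tx_seq[start_t:end_t]
    noisy = _inject_errors(rng, clean, sim.subst_rate, sim.indel_rate)
    tail = "A" * int(rng.integers(sim.polya_len[0], sim.polya_len[1] + 1))
    return SimulatedRead(
        read_id=f"{tx.transcript_id}|{rep}|{serial}",
        transcript_id=tx.transcript_id,
        replicate=rep,
        chrom=tx.location.chrom,
        strand=tx.location.strand,
        blocks=blocks,
        clean_seq=clean,
        fastq_seq=noisy + tail,
    )


def _transcript_slice_blocks(tx: AnnotationTranscript, start_t: int,
                             end_t: int) -> list[tuple[int, int]]:
    """Genomic blocks covered by transcript coordinates [start_t, end_t)."""
    exons = tx.exons if tx.location.strand == "+" else list(reversed(tx.exons))
    blocks = []
    offset = 0
    for exon in exons:
        elen = exon.end - exon.start
        lo = max(start_t, offset)
        hi = min(end_t, offset + elen)
        if lo < hi:
            if tx.location.strand == "+":
                blocks.append((exon.start + (lo - offset),
                               exon.start + (hi - offset)))
            else:
                blocks.append((exon.end - (hi - offset),
                               exon.end - (lo - offset)))
        offset += elen
    return sorted(blocks)


def _wobble_junctions(rng: np.random.Generator, blocks: list[tuple[int, int]],
                      prob: float, max_shift: int) -> list[tuple[int, int]]:
    """Slide whole junctions by up to max_shift bp (block lengths preserved
    around the gap so query length is unchanged)."""
    out = [list(b) for b in blocks]
    for j in range(len(out) - 1):
        if rng.random() >= prob:
            continue
        d = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
        left, right = out[j], out[j + 1]
        new_left_end = left[1] + d
        new_right_start = right[0] + d
        if (new_left_end - left[0] >= 5 and right[1] - new_right_start >= 5
                and new_right_start - new_left_end >= 20):
            left[1] = new_left_end
            right[0] = new_right_start
    return [tuple(b) for b in out]


_BASES = "ACGT"


def _inject_errors(rng: np.random.Generator, seq: str, subst_rate: float,
                   indel_rate: float) -> str:
    if subst_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue                                  # deletion
        if r < indel_rate:
            out.append(_BASES[rng.integers(4)])       # insertion
        if rng.random() < subst_rate:
            base = _BASES[(rng.integers(1, 4) + _BASES.find(base)) % 4]
        out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# On-disk fixture emission
# ---------------------------------------------------------------------------

def write_fixture(data: SimulatedData, out_dir: str | Path,
                  fastq_quality: int = 20) -> dict[str, object]:
    """Write genome.fa, truth.gtf and per-replicate FASTQ + truth SAM.

    Returns a dict of paths: genome, annotation, fastq (per replicate),
    truth_sam (per replicate).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_path = out_dir / "genome.fa"
    write_genome_fasta(data.genome, genome_path)
    gtf_path = out_dir / "truth.gtf"
    write_annotation_gtf(data.transcripts, gtf_path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in data.genome.items()],
    }
    refs = {name: i for i, name in enumerate(data.genome)}
    fastqs, sams = {}, {}
    qual_char = chr(33 + fastq_quality)
    for rep in sorted(data.reads_by_replicate):
        reads = data.reads_by_replicate[rep]
        fq = out_dir / f"{rep}.fastq"
        with open(fq, "w") as fh:
            for read in reads:
                fh.write(f"@{read.read_id}\n{read.fastq_seq}\n+\n"
                         f"{qual_char * len(read.fastq_seq)}\n")
        fastqs[rep] = fq
        sam = out_dir / f"{rep}.truth.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header) as bam:
            for read in reads:
                seg = pysam.AlignedSegment(bam.header)
                seg.query_name = read.read_id
                seg.reference_id = refs[read.chrom]
                seg.reference_start = read.blocks[0][0]
                seg.flag = 16 if read.strand == "-" else 0
                seg.mapping_quality = 60
                seg.cigarstring = _blocks_to_cigar(read.blocks)
                seq = read.clean_seq if read.strand == "+" \
                    else reverse_complement(read.clean_seq)
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(
                    qual_char * len(seq))
                bam.write(seg)
        sams[rep] = sam
    return {"genome": genome_path, "annotation": gtf_path,
            "fastq": fastqs, "truth_sam": sams}


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Annotation distortion
# ---------------------------------------------------------------------------

def distort_annotation(transcripts: Sequence[AnnotationTranscript],
                       shift: int = 100, seed: int = 0
                       ) -> tuple[list[AnnotationTranscript], list[str]]:
    """Shift transcript boundaries to model an imperfect annotation.

    Per transcript one of seven modifications is chosen uniformly at random:
    5' end moved *shift* bp downstream or upstream, 3' end moved downstream
    or upstream, both ends moved upstream, both moved downstream, or no
    change.  Upstream/downstream are taken in transcription direction; only
    the terminal exons move, and a shift that would cross the first/last
    splice junction truncates 1 bp short of it (shifts past the chromosome
    start clamp at 0).  Returns the modified transcripts and the case label
    per transcript.
    """
    rng = np.random.default_rng(seed)
    out, labels = [], []
    for tx in transcripts:
        case = DISTORTION_CASES[int(rng.integers(len(DISTORTION_CASES)))]
        labels.append(case)
        out.append(_apply_distortion(tx, case, shift))
    return out, labels


def _apply_distortion(tx: AnnotationTranscript, case: str, shift: int
                      ) -> AnnotationTranscript:
    if case == "none":
        return AnnotationTranscript(tx.transcript_id, tx.gene_id, tx.location,
                                    list(tx.exons))
    move5 = move3 = 0   # signed, in transcription direction (+ = downstream)
    if case in ("five_downstream", "both_downstream"):
        move5 = shift
    if case in ("five_upstream", "both_upstream"):
        move5 = -shift
    if case in ("three_downstream", "both_downstream"):
        move3 = shift
    if case in ("three_upstream", "both_upstream"):
        move3 = -shift

    exons = [[e.start, e.end] for e in tx.exons]
    strand = tx.location.strand
    multi = len(exons) > 1
    # genomic-left terminal exon holds the 5' end on "+", the 3' end on "-"
    if strand == "+":
        dleft, dright = move5, move3
    else:
        dleft, dright = -move3, -move5
    new_left = max(0, exons[0][0] + dleft)
    if new_left > exons[0][1] - 1:
        new_left = exons[0][1] - 1
    if multi and new_left > exons[0][1] - 1:
        new_left = exons[0][1] - 1
    exons[0][0] = new_left
    new_right = exons[-1][1] + dright
    if new_right < exons[-1][0] + 1:
        new_right = exons[-1][0] + 1
    exons[-1][1] = new_right
    chrom = tx.location.chrom
    new_exons = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    loc = GenomicInterval(chrom, new_exons[0].start, new_exons[-1].end, strand)
    return AnnotationTranscript(tx.transcript_id, tx.gene_id, loc, new_exons)
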