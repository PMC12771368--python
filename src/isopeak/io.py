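"""Readers and writers for the external formats the pipeline touches.

SAM/BAM goes through pysam, GTF reading through gffutils, tabular junction
files through pandas, genome access through pyfaidx.  Internal coordinates are
always 0-based half-open; the 1-based inclusive conventions of GTF and STAR
``SJ.out.tab`` are applied only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
import pysam

from .intervals import GenomicInterval, to_one_based, to_zero_based

log = logging.getLogger(__name__)

_SJ_STRAND = {0: "undefined", 1: "+", 2: "-"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentRecord:
    """One raw alignment line, lightly decoded from SAM/BAM."""

    read_id: str
    replicate: str
    is_unmapped: bool
    is_secondary: bool = False
    is_supplementary: bool = False
    chrom: str | None = None
    start: int = -1          # 0-based reference start
    end: int = -1            # 0-based exclusive reference end
    strand: str = "+"
    cigar: str = ""


@dataclass
class AnnotationTranscript:
    """A reference ("etalon") transcript with its exon chain."""

    transcript_id: str
    gene_id: str
    location: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        for i, exon in enumerate(exons):
            if exon.chrom != self.location.chrom or exon.strand != self.location.strand:
                raise ValueError(f"{self.transcript_id}: exon off transcript chrom/strand")
            if exon.start < self.location.start or exon.end > self.location.end:
                raise ValueError(f"{self.transcript_id}: exon outside transcript span")
            if i and exon.start < exons[i - 1].end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    @property
    def introns(self) -> list[GenomicInterval]:
        """Implied introns: gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out

    @property
    def five_prime(self) -> int:
        loc = self.location
        return loc.start if loc.strand == "+" else loc.end - 1

    @property
    def three_prime(self) -> int:
        loc = self.location
        return loc.end - 1 if loc.strand == "+" else loc.start


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, replicate: str) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file.

    Unmapped records are passed through flagged as unmapped; mapped records
    missing a CIGAR are skipped with a warning.  Truncated or unreadable
    files raise ``OSError``/``ValueError`` naming the file.
    """
    path = str(path)
    try:
        handle = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignments from {path}: {exc}") from exc
    with handle:
        try:
            for rec in handle:
                if rec.is_unmapped:
                    yield AlignmentRecord(rec.query_name, replicate, True)
                    continue
                if rec.cigarstring is None:
                    log.warning("mapped record %s in %s has no CIGAR; skipped",
                                rec.query_name, path)
                    continue
                yield AlignmentRecord(
                    read_id=rec.query_name,
                    replicate=replicate,
                    is_unmapped=False,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring,
                )
        except OSError as exc:
            raise OSError(f"truncated or unreadable alignment file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Splice-junction tables
# ---------------------------------------------------------------------------

def read_star_junctions(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Parse splice-junction files into a 0-based half-open intron table.

    Two dialects are accepted, distinguished by column count: the 9-column
    STAR ``SJ.out.tab`` (chrom, 1-based first/last intronic base, strand code
    0/1/2, ...) and a minimal 4-column TSV (chrom, first, last, strand symbol
    ``+``/``-``/``.``) using the same 1-based inclusive convention.

    Returns a DataFrame with columns chrom, start, end, strand, sample; one
    row per input row, provenance kept in ``sample`` (the file stem, suffixed
    on collision).
    """
    frames = []
    seen: dict[str, int] = {}
    for path in paths:
        path = Path(path)
        label = path.stem
        if label in seen:
            seen[label] += 1
            label = f"{label}.{seen[label]}"
        else:
            seen[label] = 0
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] >= 9:
            strands = df[3].map(_SJ_STRAND)
            if strands.isna().any():
                raise ValueError(f"{path}: invalid strand code in column 4")
        elif df.shape[1] >= 4:
            strands = df[3].map({"+": "+", "-": "-", ".": "undefined",
                                 0: "undefined", 1: "+", 2: "-"})
            if strands.isna().any():
                raise ValueError(f"{path}: invalid strand symbol in column 4")
        else:
            raise ValueError(f"{path}: expected >=4 tab-separated columns")
        start, end = to_zero_based(df[1].astype(int), df[2].astype(int))
        frames.append(pd.DataFrame({
            "chrom": df[0], "start": start, "end": end,
            "strand": strands, "sample": label,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "sample"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[AnnotationTranscript]:
    """Read transcripts (with exon chains) from a GTF file."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    transcripts = []
    by_tx: dict[str, list] = {}
    tx_feats: dict[str, gffutils.Feature] = {}
    for feat in db.all_features():
        if feat.featuretype == "exon":
            by_tx.setdefault(feat.attributes["transcript_id"][0], []).append(feat)
        elif feat.featuretype in ("transcript", "mRNA"):
            tx_feats[feat.attributes["transcript_id"][0]] = feat
    for tx_id, exon_feats in sorted(by_tx.items()):
        exon_feats.sort(key=lambda f: f.start)
        strand = exon_feats[0].strand
        chrom = exon_feats[0].seqid
        exons = [GenomicInterval(chrom, *to_zero_based(f.start, f.end), strand)
                 for f in exon_feats]
        tx = tx_feats.get(tx_id)
        if tx is not None:
            loc = GenomicInterval(tx.seqid, *to_zero_based(tx.start, tx.end), tx.strand)
            gene_id = tx.attributes["gene_id"][0]
        else:
            loc = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            gene_id = exon_feats[0].attributes["gene_id"][0]
        transcripts.append(AnnotationTranscript(tx_id, gene_id, loc, exons))
    return transcripts


def write_gtf(genes: Iterable, path: str | Path, source: str = "isopeak") -> None:
    """Write gene models as GTF (gene/transcript/exon features).

    ``genes`` is an iterable of :class:`~isopeak.isoforms.GeneModel`.
    Transcripts are sorted by chrom then start; coordinates are converted to
    1-based inclusive.  An isoform with no exons is a violated invariant and
    raises ``ValueError``.
    """
    lines = []
    for gene in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
        g1, g2 = to_one_based(gene.span.start, gene.span.end)
        lines.append(_gtf_line(gene.span.chrom, source, "gene", g1, g2,
                               gene.span.strand,
                               f'gene_id "{gene.gene_id}";'))
        for iso in sorted(gene.isoforms, key=lambda i: (i.span.start, i.isoform_id)):
            if not iso.exons:
                raise ValueError(f"isoform {iso.isoform_id} has zero exons")
            t1, t2 = to_one_based(iso.exons[0].start, iso.exons[-1].end)
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{iso.isoform_id}";'
            lines.append(_gtf_line(iso.span.chrom, source, "transcript",
                                   t1, t2, iso.span.strand, attrs))
            for exon in iso.exons:   # ascending genomic order, both strands
                e1, e2 = to_one_based(exon.start, exon.end)
                lines.append(_gtf_line(exon.chrom, source, "exon",
                                       e1, e2, exon.strand, attrs))
    Path(path).write_text("".join(lines))


def _gtf_line(chrom, source, feature, start1, end1, strand, attrs) -> str:
    return f"{chrom}\t{source}\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"


def write_annotation_gtf(transcripts: Iterable[AnnotationTranscript],
                         path: str | Path, source: str = "isopeak") -> None:
    """Write :class:`AnnotationTranscript` objects as GTF (used by the simulator)."""
    lines = []
    for tx in sorted(transcripts, key=lambda t: (t.location.chrom, t.location.start,
                                                 t.transcript_id)):
        t1, t2 = to_one_based(tx.location.start, tx.location.end)
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        lines.append(_gtf_line(tx.location.chrom, source, "transcript",
                               t1, t2, tx.location.strand, attrs))
        for exon in tx.exons:
            e1, e2 = to_one_based(exon.start, exon.end)
            lines.append(_gtf_line(exon.chrom, source, "exon", e1, e2,
                                   exon.strand, attrs))
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
    return str(seq[start:end]).upper()


def isoform_sequence(isoform, genome) -> str:
    """Spliced isoform sequence: exon concatenation, minus strand reverse-complemented.

    ``genome`` is any mapping chrom -> sliceable sequence (a ``pyfaidx.Fasta``
    or a plain dict of strings).
    """
    exons = isoform.exons
    seq = "".join(_fetch(genome, e.chrom, e.start, e.end) for e in exons)
    if exons and exons[0].strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_isoform_fasta(genes: Iterable, genome, path: str | Path,
                        width: int = 80) -> None:
    """Write spliced isoform sequences; headers carry isoform and gene IDs."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            for iso in sorted(gene.isoforms, key=lambda i: (i.span.start, i.isoform_id)):
                seq = isoform_sequence(iso, genome)
                fh.write(f">{iso.isoform_id} gene={gene.gene_id}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def write_gene_fasta(genes: Iterable, genome, path: str | Path,
                     width: int = 80) -> None:
    """Write unspliced gene-span sequences (minus strand reverse-complemented)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            seq = _fetch(genome, gene.span.chrom, gene.span.start, gene.span.end)
            if gene.span.strand == "-":
                seq = reverse_complement(seq)
            fh.write(f">{gene.gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genome_fasta(chroms: dict[str, str], path: str | Path,
                       width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Diagnostic tracks
# ---------------------------------------------------------------------------

def write_bedgraph(counts: dict[int, int], chrom: str, path: str | Path) -> None:
    """Dump a sparse single-nucleotide count track as bedGraph."""
    with open(path, "w") as fh:
        for pos in sorted(counts):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{counts[pos]}\n")


def write_peaks_bed(peaks: Iterable, path: str | Path) -> None:
    """Dump end peaks as BED6+1 (name=peak_id, score=pooled count, col7=summit)."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.region.chrom, p.region.start)):
            fh.write(f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t"
                     f"{p.peak_id}\t{p.pooled_count}\t{p.region.strand}\t{p.summit}\n")
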