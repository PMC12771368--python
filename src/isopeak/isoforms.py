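"""Isoform and gene reconstruction.

Reads whose 5' and 3' ends fall into called TSS and PA peaks are grouped by
the triple (TSS peak, exact intron chain, PA peak); groups passing the
replicate-concordance filter become isoforms, isoforms are clustered into
genes by the 80%-of-shorter span-overlap rule, genes are optionally named
from an annotation, and (optionally) minor isoforms below a fraction of the
gene's major isoform are removed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .end_peaks import FIVE_PRIME, THREE_PRIME, EndPeak, PeakIndex
from .intervals import GenomicInterval
from .io import AnnotationTranscript
from .preprocess import AlignedRead

log = logging.getLogger(__name__)

NOVEL_GENE_PREFIX = "IPKG"

REJECT_NO_TSS = "no_tss"
REJECT_NO_PA = "no_pa"


@dataclass
class IsoformModel:
    """A group of reads sharing (TSS peak, intron chain, PA peak)."""

    isoform_id: str
    tss_peak: EndPeak
    pa_peak: EndPeak
    introns: tuple[GenomicInterval, ...]
    counts: dict[str, int]
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def chain_key(self) -> tuple:
        return tuple((i.start, i.end) for i in self.introns)


@dataclass
class GeneModel:
    """A cluster of isoforms joined by the 80%-of-shorter overlap rule."""

    gene_id: str
    span: GenomicInterval
    isoforms: list[IsoformModel]
    annotation_id: str | None = None


# ---------------------------------------------------------------------------
# End assignment and grouping
# ---------------------------------------------------------------------------

def assign_ends(read: AlignedRead, tss_index: PeakIndex, pa_index: PeakIndex
                ) -> tuple[EndPeak, EndPeak] | str:
    """Locate a read's 5' end in a TSS peak and its 3' end in a PA peak.

    Returns the peak pair, or a rejection reason when either end falls
    outside every peak region of its track.
    """
    loc = read.location
    tss = tss_index.find(loc.chrom, loc.strand, read.five_prime)
    if tss is None:
        return REJECT_NO_TSS
    pa = pa_index.find(loc.chrom, loc.strand, read.three_prime)
    if pa is None:
        return REJECT_NO_PA
    return tss, pa


@dataclass
class IsoformCandidate:
    tss_peak: EndPeak
    pa_peak: EndPeak
    introns: tuple[GenomicInterval, ...]
    counts: dict[str, int]
    chrom: str
    strand: str


def group_reads(reads: Sequence[AlignedRead], tss_index: PeakIndex,
                pa_index: PeakIndex
                ) -> tuple[list[IsoformCandidate], list[tuple[str, str]]]:
    """Group peak-assigned reads into isoform candidates.

    The grouping key is (TSS peak id, exact intron chain, PA peak id);
    single-exon reads have empty chains and group by end peaks alone.
    Returns the candidates plus (read_id, reason) pairs for rejected reads.
    """
    groups: dict[tuple, IsoformCandidate] = {}
    rejects: list[tuple[str, str]] = []
    for read in reads:
        assigned = assign_ends(read, tss_index, pa_index)
        if isinstance(assigned, str):
            rejects.append((read.read_id, assigned))
            continue
        tss, pa = assigned
        chain = tuple(read.introns)
        key = (tss.peak_id, tuple((i.start, i.end) for i in chain), pa.peak_id)
        cand = groups.get(key)
        if cand is None:
            cand = IsoformCandidate(tss, pa, chain, {}, read.location.chrom,
                                    read.location.strand)
            groups[key] = cand
        cand.counts[read.replicate] = cand.counts.get(read.replicate, 0) + 1
    ordered = [groups[k] for k in sorted(groups)]
    log.info("grouping: %d assigned candidates, %d rejected reads",
             len(ordered), len(rejects))
    return ordered, rejects


def filter_by_replicates(candidates: Sequence[IsoformCandidate],
                         high_count: int = 5, low_count: int = 1,
                         ) -> list[IsoformCandidate]:
    """Replicate-concordance filter.

    A candidate is retained iff some replicate has >= *high_count* reads and
    a *different* replicate has >= *low_count* reads (equivalently: the
    largest count >= high_count and the second largest >= low_count).
    """
    out = []
    for cand in candidates:
        counts = sorted(cand.counts.values(), reverse=True)
        counts += [0] * (2 - len(counts))
        if counts[0] >= high_count and counts[1] >= low_count:
            out.append(cand)
    log.info("replicate filter (>=%d and >=%d elsewhere): %d -> %d isoforms",
             high_count, low_count, len(candidates), len(out))
    return out


# ---------------------------------------------------------------------------
# Structural assembly
# ---------------------------------------------------------------------------

def candidate_span(cand: IsoformCandidate) -> GenomicInterval:
    """Isoform span: outer bounds of the two peak regions."""
    start = min(cand.tss_peak.region.start, cand.pa_peak.region.start)
    end = max(cand.tss_peak.region.end, cand.pa_peak.region.end)
    return GenomicInterval(cand.chrom, start, end, cand.strand)


def build_exons(cand: IsoformCandidate) -> list[GenomicInterval] | None:
    """Representative exon chain with peak summits as terminal coordinates.

    The 5'-terminal exon starts (in transcription direction) at the TSS
    summit and the 3'-terminal exon ends at the PA summit.  Returns None
    when the summit ordering is inconsistent with the intron chain (such an
    isoform is dropped with a warning).
    """
    if cand.strand == "+":
        left, right = cand.tss_peak.summit, cand.pa_peak.summit
    else:
        left, right = cand.pa_peak.summit, cand.tss_peak.summit
    if left > right:
        return None
    bounds = [left]
    for intron in cand.introns:
        bounds.extend((intron.start, intron.end))
    bounds.append(right + 1)
    exons = []
    for s, e in zip(bounds[::2], bounds[1::2]):
        if s >= e:
            return None
        exons.append(GenomicInterval(cand.chrom, s, e, cand.strand))
    return exons


# ---------------------------------------------------------------------------
# Gene clustering and naming
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def spans_linked(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    """The 80%-of-shorter rule: overlap >= frac * min(len(a), len(b))."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    return a.overlap(b) >= frac * min(len(a), len(b))


def cluster_genes(isoforms: Sequence[IsoformModel], gene_overlap_frac: float = 0.8
                  ) -> list[GeneModel]:
    """Connected components of the pairwise span-overlap relation.

    Two isoforms are related when the overlap of their spans covers at least
    *gene_overlap_frac* of the shorter span (same chrom and strand only);
    genes are the transitive closure, with the gene span the componentwise
    min/max.  Gene ids are assigned later.
    """
    uf = _UnionFind(len(isoforms))
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, iso in enumerate(isoforms):
        by_key[(iso.span.chrom, iso.span.strand)].append(i)
    for key, idxs in by_key.items():
        idxs.sort(key=lambda i: isoforms[i].span.start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if gene_overlap_frac > 0 and \
                        isoforms[j].span.start >= isoforms[i].span.end:
                    break
                if spans_linked(isoforms[i].span, isoforms[j].span,
                                gene_overlap_frac):
                    uf.union(i, j)
    components: dict[int, list[int]] = defaultdict(list)
    for i in range(len(isoforms)):
        components[uf.find(i)].append(i)
    genes = []
    for root in sorted(components):
        members = [isoforms[i] for i in components[root]]
        start = min(m.span.start for m in members)
        end = max(m.span.end for m in members)
        span = GenomicInterval(members[0].span.chrom, start, end,
                               members[0].span.strand)
        members.sort(key=lambda m: (-m.total_count, m.span.start, m.chain_key))
        genes.append(GeneModel("", span, members))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.span.strand))
    return genes


def assign_gene_ids(genes: Sequence[GeneModel],
                    annotation: Iterable[AnnotationTranscript] | None,
                    gene_overlap_frac: float = 0.8) -> None:
    """Name genes from the annotation via the 80%-of-shorter rule.

    Among same-strand annotated genes passing the rule, the one with maximal
    absolute overlap wins (ties lexicographic); genes without a candidate
    get a stable coordinate-derived novel id.  Isoform ids are suffixed
    ``.i<k>`` in descending read-count order.
    """
    from .downsample import gene_intervals
    ann = gene_intervals(annotation) if annotation is not None else []
    for gene in genes:
        best: tuple[int, str] | None = None
        for ann_id, span in ann:
            if span.strand != gene.span.strand:
                continue
            if spans_linked(gene.span, span, gene_overlap_frac):
                key = (-gene.span.overlap(span), ann_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            gene.annotation_id = best[1]
            gene.gene_id = best[1]
        else:
            gene.gene_id = (f"{NOVEL_GENE_PREFIX}_{gene.span.chrom}_"
                            f"{gene.span.start}_{gene.span.strand}")
        for k, iso in enumerate(gene.isoforms, 1):
            iso.isoform_id = f"{gene.gene_id}.i{k}"


def filter_minor_isoforms(gene: GeneModel, minor_frac: float = 0.01) -> GeneModel:
    """Drop isoforms at or below *minor_frac* of the gene's major isoform.

    The major isoform (maximal summed read count; all tied maxima are major)
    is always kept; any other isoform is kept iff its total count is
    strictly greater than ``minor_frac * major_total``.
    """
    major_total = max(iso.total_count for iso in gene.isoforms)
    kept = [iso for iso in gene.isoforms
            if iso.total_count == major_total
            or iso.total_count > minor_frac * major_total]
    return GeneModel(gene.gene_id, gene.span, kept, gene.annotation_id)


# ---------------------------------------------------------------------------
# Assembly driver and emission
# ---------------------------------------------------------------------------

def build_isoforms(candidates: Sequence[IsoformCandidate]) -> list[IsoformModel]:
    """Materialise filtered candidates into isoform models with exon chains.

    Candidates whose peak summits are inconsistent with their intron chain
    are dropped with a warning.
    """
    out = []
    for cand in candidates:
        exons = build_exons(cand)
        if exons is None:
            log.warning("isoform with inconsistent summit/chain ordering at "
                        "%s:%d dropped", cand.chrom, cand.tss_peak.summit)
            continue
        out.append(IsoformModel(
            isoform_id="",
            tss_peak=cand.tss_peak,
            pa_peak=cand.pa_peak,
            introns=cand.introns,
            counts=dict(cand.counts),
            span=candidate_span(cand),
            exons=exons,
        ))
    return out


def write_counts(genes: Sequence[GeneModel], replicates: Sequence[str],
                 path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("isoform_id\tgene_id\t" + "\t".join(replicates) + "\n")
        for gene in genes:
            for iso in gene.isoforms:
                row = "\t".join(str(iso.counts.get(r, 0)) for r in replicates)
                fh.write(f"{iso.isoform_id}\t{gene.gene_id}\t{row}\n")


def write_rejects(rejects: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in rejects:
            fh.write(f"{read_id}\t{reason}\n")


def write_pseudo_alignments(genes: Sequence[GeneModel], path: str | Path,
                            width: int = 100) -> None:
    """Per gene, one text row per isoform drawing exon blocks over the gene span.

    Exons are ``=``, introns ``-``, peak-region flanks outside the summits
    ``.``; the isoform's total read count is appended.
    """
    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            scale = max(1, -(-len(span) // width))  # bp per character
            fh.write(f">{gene.gene_id} {span.chrom}:{span.start}-{span.end}"
                     f"({span.strand})\n")
            for iso in gene.isoforms:
                ncols = -(-len(span) // scale)
                row = ["."] * ncols
                first, last = iso.exons[0].start, iso.exons[-1].end
                for pos in range(first, last):
                    row[(pos - span.start) // scale] = "-"
                for exon in iso.exons:
                    for pos in range(exon.start, exon.end):
                        row[(pos - span.start) // scale] = "="
                fh.write(f"{''.join(row)}  {iso.isoform_id} "
                         f"n={iso.total_count}\n")
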