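"""Optional read downsampling over highly expressed genes or regions.

Highly expressed genes yield many reads derived from tattered RNA whose 5'
ends are scattered across the gene body; capping the read count per gene
(annotation mode) or the per-base coverage (annotation-free mode) keeps such
noise from swamping end-peak detection.
"""

from __future__ import annotations

import logging
import zlib
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .io import AnnotationTranscript
from .preprocess import AlignedRead

log = logging.getLogger(__name__)


def derive_rng(seed: int, *tokens) -> np.random.Generator:
    """A reproducible per-scope generator, derived by stable hashing.

    Parallel or out-of-order execution over (replicate, chrom, strand)
    scopes stays reproducible because each scope owns its own stream.
    """
    material = ":".join([str(seed), *map(str, tokens)]).encode()
    return np.random.default_rng(zlib.crc32(material))


def gene_intervals(annotation: Iterable[AnnotationTranscript]
                   ) -> list[tuple[str, GenomicInterval]]:
    """Gene spans (min/max over each gene's transcripts), sorted by id."""
    spans: dict[str, list[AnnotationTranscript]] = defaultdict(list)
    for tx in annotation:
        spans[tx.gene_id].append(tx)
    out = []
    for gene_id in sorted(spans):
        txs = spans[gene_id]
        chrom = txs[0].location.chrom
        strand = txs[0].location.strand
        start = min(t.location.start for t in txs)
        end = max(t.location.end for t in txs)
        out.append((gene_id, GenomicInterval(chrom, start, end, strand)))
    return out


def attribute_reads(reads: Sequence[AlignedRead],
                    genes: Sequence[tuple[str, GenomicInterval]]
                    ) -> dict[str, list[int]]:
    """Attribute each read to at most one gene.

    The gene with the largest absolute overlap with the read span wins; ties
    go to the larger overlap fraction of the read, then to the
    lexicographically smaller gene id.  Reads overlapping no gene are left
    unattributed.  Attribution is strand-agnostic.  Returns gene_id ->
    indices into *reads*.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene_id, span in genes:
        trees[span.chrom].addi(span.start, span.end, gene_id)
    by_gene: dict[str, list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        loc = read.location
        hits = trees[loc.chrom].overlap(loc.start, loc.end)
        if not hits:
            continue
        def score(hit):
            ov = min(hit.end, loc.end) - max(hit.begin, loc.start)
            return (-ov, -ov / len(loc), hit.data)
        best = min(hits, key=score)
        by_gene[best.data].append(idx)
    return by_gene


def downsample_annotated(reads: Sequence[AlignedRead],
                         annotation: Iterable[AnnotationTranscript],
                         cap: int = 1000, min_gene_reads: int = 5,
                         seed: int = 0, replicate: str = "") -> list[AlignedRead]:
    """Cap the number of reads per annotated gene for one replicate.

    Genes with fewer than *min_gene_reads* attributed reads are ignored;
    genes with more than *cap* reads keep exactly *cap*, chosen uniformly
    without replacement; everything else (including unattributed reads) is
    untouched.
    """
    genes = gene_intervals(annotation)
    by_gene = attribute_reads(reads, genes)
    drop: set[int] = set()
    n_capped = 0
    for gene_id in sorted(by_gene):
        idxs = by_gene[gene_id]
        if len(idxs) < min_gene_reads or len(idxs) <= cap:
            continue
        rng = derive_rng(seed, "annotated", replicate, gene_id)
        keep = set(rng.choice(len(idxs), size=cap, replace=False).tolist())
        drop.update(idx for k, idx in enumerate(idxs) if k not in keep)
        n_capped += 1
    out = [r for i, r in enumerate(reads) if i not in drop]
    log.info("annotated downsampling (%s): %d genes capped, %d -> %d reads",
             replicate, n_capped, len(reads), len(out))
    return out


def downsample_annotation_free(reads: Sequence[AlignedRead], cap: int = 1000,
                               seed: int = 0, replicate: str = ""
                               ) -> list[AlignedRead]:
    """Cap per-base coverage for one replicate without an annotation.

    Coverage is computed per (chrom, strand) from read spans.  Within each
    maximal run of positions whose coverage exceeds *cap*, reads covering
    the position of current maximum coverage are removed one at a time
    (uniformly at random, seeded per scope) until the run's maximum drops
    to *cap*.
    """
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        by_key[(read.location.chrom, read.location.strand)].append(idx)
    drop: set[int] = set()
    for key in sorted(by_key):
        chrom, strand = key
        idxs = by_key[key]
        rng = derive_rng(seed, "free", replicate, chrom, strand)
        drop.update(_reduce_runs([reads[i] for i in idxs], idxs, cap, rng))
    out = [r for i, r in enumerate(reads) if i not in drop]
    log.info("annotation-free downsampling (%s): %d -> %d reads",
             replicate, len(reads), len(out))
    return out


def _reduce_runs(group: list[AlignedRead], idxs: list[int], cap: int,
                 rng: np.random.Generator) -> set[int]:
    """Indices (into the original read list) to drop for one (chrom, strand)."""
    if not group:
        return set()
    lo = min(r.location.start for r in group)
    hi = max(r.location.end for r in group)
    cov = np.zeros(hi - lo + 1, dtype=np.int64)
    for r in group:
        cov[r.location.start - lo] += 1
        cov[r.location.end - lo] -= 1
    cov = np.cumsum(cov)[:-1]  # coverage at positions lo..hi-1

    drop: set[int] = set()
    alive = list(range(len(group)))
    # maximal runs of positions with coverage > cap, found once up front:
    # removals only lower coverage, so no new runs can appear.
    over = cov > cap
    pos = 0
    runs = []
    while pos < len(over):
        if over[pos]:
            start = pos
            while pos < len(over) and over[pos]:
                pos += 1
            runs.append((start, pos))
        else:
            pos += 1
    for run_start, run_end in runs:
        while True:
            seg = cov[run_start:run_end]
            peak_off = int(np.argmax(seg))
            if seg[peak_off] <= cap:
                break
            peak_pos = lo + run_start + peak_off
            covering = [k for k in alive
                        if group[k].location.start <= peak_pos < group[k].location.end]
            victim = covering[int(rng.integers(len(covering)))]
            alive.remove(victim)
            drop.add(idxs[victim])
            r = group[victim].location
            cov[r.start - lo:r.end - lo] -= 1
    return drop
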