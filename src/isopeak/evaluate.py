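"""Transcript-level evaluation against an etalon annotation.

Two conventions are supported for transcript termini: *points* mode, where a
prediction is correct only if its 5' point, intron chain and 3' point are
identical to an etalon transcript, and *peaks* mode, where the intron chain
must be identical and the etalon's terminal points must fall inside the
prediction's 5'/3' end regions.  Point-based predictions (from tools that do
not call end peaks) are expanded to regions using per-gene halfwidths derived
from a reference run of this pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .end_peaks import EndPeak
from .io import AnnotationTranscript
from .isoforms import GeneModel

log = logging.getLogger(__name__)

Chain = tuple[tuple[int, int], ...]


@dataclass
class Prediction:
    """One predicted isoform in evaluator terms."""

    pred_id: str
    chrom: str
    strand: str
    chain: Chain
    five_point: int
    three_point: int
    five_region: tuple[int, int] | None = None   # half-open
    three_region: tuple[int, int] | None = None
    n_replicates: int | None = None
    span: tuple[int, int] | None = None


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    matches: list[tuple[str, str | None, str]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


# ---------------------------------------------------------------------------
# Prediction adapters
# ---------------------------------------------------------------------------

def predictions_from_genes(genes: Iterable[GeneModel]) -> list[Prediction]:
    """Evaluator view of this pipeline's gene models (native end regions)."""
    preds = []
    for gene in genes:
        for iso in gene.isoforms:
            preds.append(Prediction(
                pred_id=iso.isoform_id,
                chrom=iso.span.chrom,
                strand=iso.span.strand,
                chain=iso.chain_key,
                five_point=iso.tss_peak.summit,
                three_point=iso.pa_peak.summit,
                five_region=(iso.tss_peak.region.start, iso.tss_peak.region.end),
                three_region=(iso.pa_peak.region.start, iso.pa_peak.region.end),
                n_replicates=sum(1 for c in iso.counts.values() if c > 0),
                span=(iso.span.start, iso.span.end),
            ))
    return preds


def predictions_from_transcripts(transcripts: Iterable[AnnotationTranscript]
                                 ) -> list[Prediction]:
    """Evaluator view of a point-based GTF (competitor tools, annotations)."""
    preds = []
    for tx in transcripts:
        preds.append(Prediction(
            pred_id=tx.transcript_id,
            chrom=tx.location.chrom,
            strand=tx.location.strand,
            chain=tuple((i.start, i.end) for i in tx.introns),
            five_point=tx.five_prime,
            three_point=tx.three_prime,
            span=(tx.location.start, tx.location.end),
        ))
    return preds


def _etalon_entries(etalons: Iterable[AnnotationTranscript]):
    for tx in etalons:
        yield (tx.transcript_id, tx.location.chrom, tx.location.strand,
               tuple((i.start, i.end) for i in tx.introns),
               tx.five_prime, tx.three_prime)


def _replicate_filter(predictions: Sequence[Prediction],
                      min_replicates: int = 2) -> list[Prediction]:
    if any(p.n_replicates is None for p in predictions):
        if any(p.n_replicates is not None for p in predictions):
            log.warning("mixed replicate info; replicate restriction skipped")
        else:
            log.warning("no replicate info on predictions; "
                        "replicate restriction skipped")
        return list(predictions)
    return [p for p in predictions if p.n_replicates >= min_replicates]


# ---------------------------------------------------------------------------
# Points mode
# ---------------------------------------------------------------------------

def match_points(predictions: Sequence[Prediction],
                 etalons: Iterable[AnnotationTranscript],
                 min_replicates: int = 2) -> EvalReport:
    """Exact-identity matching of 5' point, intron chain and 3' point.

    Each etalon transcript matches at most one prediction (greedy in
    prediction order; duplicate predictions count as false positives).  When
    all predictions carry replicate information, only those detected in at
    least *min_replicates* replicates are scored.
    """
    preds = _replicate_filter(predictions, min_replicates)
    available: dict[tuple, list[str]] = {}
    n_etalons = 0
    for tx_id, chrom, strand, chain, five, three in _etalon_entries(etalons):
        n_etalons += 1
        available.setdefault((chrom, strand, chain, five, three), []).append(tx_id)
    report = EvalReport(0, 0, 0)
    for pred in preds:
        key = (pred.chrom, pred.strand, pred.chain, pred.five_point,
               pred.three_point)
        bucket = available.get(key)
        if bucket:
            report.tp += 1
            report.matches.append((pred.pred_id, bucket.pop(0), "tp"))
        else:
            report.fp += 1
            report.matches.append((pred.pred_id, None, "fp"))
    report.fn = n_etalons - report.tp
    return report


# ---------------------------------------------------------------------------
# Peaks mode
# ---------------------------------------------------------------------------

def gene_halfwidths(reference_genes: Iterable[GeneModel]
                    ) -> list[tuple[str, str, tuple[int, int], int]]:
    """Per reference gene: (chrom, strand, span, N) with N the maximal end-peak
    length over all the gene's isoforms."""
    out = []
    for gene in reference_genes:
        n = 0
        for iso in gene.isoforms:
            n = max(n, len(iso.tss_peak.region), len(iso.pa_peak.region))
        out.append((gene.span.chrom, gene.span.strand,
                    (gene.span.start, gene.span.end), n))
    return out


def _expand_point_prediction(pred: Prediction,
                             halfwidths, min_frac: float = 0.1) -> Prediction:
    """Give a point-based prediction end regions of +-N/2 around each point.

    The gene providing N is the one whose span intersects more than
    *min_frac* of the prediction's span (largest overlap wins); with no such
    gene the halfwidth defaults to 0 (logged).
    """
    span = pred.span or (min(pred.five_point, pred.three_point),
                         max(pred.five_point, pred.three_point) + 1)
    best_n, best_ov = None, 0
    for chrom, strand, (gs, ge), n in halfwidths or []:
        if chrom != pred.chrom or strand != pred.strand:
            continue
        ov = min(ge, span[1]) - max(gs, span[0])
        if ov > min_frac * (span[1] - span[0]) and ov > best_ov:
            best_n, best_ov = n, ov
    if best_n is None:
        log.debug("prediction %s overlaps no reference gene; halfwidth 0",
                  pred.pred_id)
        best_n = 0
    hw = best_n // 2
    pred.five_region = (pred.five_point - hw, pred.five_point + hw + 1)
    pred.three_region = (pred.three_point - hw, pred.three_point + hw + 1)
    return pred


def match_peaks(predictions: Sequence[Prediction],
                etalons: Iterable[AnnotationTranscript],
                reference_genes: Iterable[GeneModel] | None = None,
                min_replicates: int = 2) -> EvalReport:
    """Region-containment matching: identical intron chain, etalon terminal
    points inside the prediction's end regions.

    Predictions without native end regions are expanded around their points
    using per-gene halfwidths from *reference_genes* (see
    :func:`gene_halfwidths`).
    """
    preds = _replicate_filter(predictions, min_replicates)
    halfwidths = gene_halfwidths(reference_genes) if reference_genes else []
    expanded = []
    for pred in preds:
        if pred.five_region is None or pred.three_region is None:
            pred = _expand_point_prediction(pred, halfwidths)
        expanded.append(pred)
    by_chain: dict[tuple, list[tuple[str, int, int]]] = {}
    n_etalons = 0
    for tx_id, chrom, strand, chain, five, three in _etalon_entries(etalons):
        n_etalons += 1
        by_chain.setdefault((chrom, strand, chain), []).append((tx_id, five, three))
    report = EvalReport(0, 0, 0)
    for pred in expanded:
        bucket = by_chain.get((pred.chrom, pred.strand, pred.chain), [])
        hit = None
        for k, (tx_id, five, three) in enumerate(bucket):
            if (pred.five_region[0] <= five < pred.five_region[1]
                    and pred.three_region[0] <= three < pred.three_region[1]):
                hit = k
                break
        if hit is not None:
            tx_id, _, _ = bucket.pop(hit)
            report.tp += 1
            report.matches.append((pred.pred_id, tx_id, "tp"))
        else:
            report.fp += 1
            report.matches.append((pred.pred_id, None, "fp"))
    report.fn = n_etalons - report.tp
    return report


# ---------------------------------------------------------------------------
# Peak-set comparison
# ---------------------------------------------------------------------------

@dataclass
class PeakComparison:
    peak_id: str
    label: str                  # intersecting | proximal | unsupported
    intersection_rate: float
    distance: int | None


def compare_peak_sets(set_a: Sequence[EndPeak], set_b: Sequence[EndPeak],
                      proximity: int = 10
                      ) -> tuple[list[PeakComparison], dict[str, float]]:
    """Classify every A peak against B (e.g. long-read TSS peaks vs CAGE).

    A peak is *intersecting* when it overlaps a B peak by >= 1 bp (the
    intersection rate is the overlapped fraction of the A peak's length),
    *proximal* when the nearest B-peak edge is within *proximity* bp, else
    *unsupported*.  The summary holds label fractions and the median
    distance of proximal peaks.
    """
    by_key: dict[tuple[str, str], list[EndPeak]] = {}
    for b in set_b:
        by_key.setdefault((b.region.chrom, b.region.strand), []).append(b)
    records = []
    for a in set_a:
        bs = by_key.get((a.region.chrom, a.region.strand), [])
        overlap = 0
        min_dist = None
        for b in bs:
            ov = a.region.overlap(b.region)
            if ov > 0:
                overlap += ov
            else:
                dist = max(b.region.start - a.region.end,
                           a.region.start - b.region.end)
                if min_dist is None or dist < min_dist:
                    min_dist = dist
        if overlap > 0:
            records.append(PeakComparison(
                a.peak_id, "intersecting",
                min(1.0, overlap / len(a.region)), None))
        elif min_dist is not None and min_dist <= proximity:
            records.append(PeakComparison(a.peak_id, "proximal", 0.0, min_dist))
        else:
            records.append(PeakComparison(a.peak_id, "unsupported", 0.0,
                                          min_dist))
    n = len(records) or 1
    prox = [r.distance for r in records if r.label == "proximal"]
    summary = {
        "frac_intersecting": sum(r.label == "intersecting" for r in records) / n,
        "frac_proximal": sum(r.label == "proximal" for r in records) / n,
        "frac_unsupported": sum(r.label == "unsupported" for r in records) / n,
        "median_proximal_distance": float(median(prox)) if prox else float("nan"),
    }
    return records, summary
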