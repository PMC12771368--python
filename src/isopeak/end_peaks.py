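"""TSS and polyadenylation-site detection by end-peak calling.

Each uniquely mapped read contributes exactly one 5' and one 3' position to
strand-specific single-nucleotide coverage tracks, kept per replicate.
Positions covered in fewer than the required number of replicates are
discarded, the remaining raw counts are pooled (no normalisation), and pooled
positions above a cutoff are merged into unidirectional tag clusters — the
TSS / PA peaks — each with a summit at its pooled-count maximum.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomicInterval
from .preprocess import AlignedRead

log = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

TrackKey = tuple[str, str, str]  # (chrom, strand, end_type)


@dataclass
class EndPeak:
    """A called TSS or PA region on one strand."""

    peak_id: str
    region: GenomicInterval
    end_type: str
    summit: int
    pooled_count: int
    per_replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.region.start <= self.summit < self.region.end:
            raise ValueError(f"summit {self.summit} outside region of {self.peak_id}")


def read_end_position(read: AlignedRead, end_type: str) -> int:
    if end_type == FIVE_PRIME:
        return read.five_prime
    if end_type == THREE_PRIME:
        return read.three_prime
    raise ValueError(f"unknown end type {end_type!r}")


def end_coverage(reads: Iterable[AlignedRead], end_type: str
                 ) -> dict[tuple[str, str], Counter]:
    """Single-nucleotide read-end counts per (chrom, strand).

    On "+" the 5' end is ``location.start`` and the 3' end is
    ``location.end - 1``; on "-" the two are swapped.  Every read contributes
    exactly one position, so counts sum to the number of reads.
    """
    tracks: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for read in reads:
        loc = read.location
        tracks[(loc.chrom, loc.strand)][read_end_position(read, end_type)] += 1
    return dict(tracks)


def build_end_tracks(reads_by_replicate: dict[str, Sequence[AlignedRead]]
                     ) -> dict[TrackKey, dict[str, Counter]]:
    """Per-replicate end tracks for all four (end type x strand) combinations."""
    tracks: dict[TrackKey, dict[str, Counter]] = defaultdict(dict)
    for replicate, reads in reads_by_replicate.items():
        for end_type in (FIVE_PRIME, THREE_PRIME):
            for (chrom, strand), counts in end_coverage(reads, end_type).items():
                tracks[(chrom, strand, end_type)][replicate] = counts
    return dict(tracks)


def pool_with_support(rep_tracks: dict[str, Counter], n_replicates: int,
                      support_min_replicates: int = 2) -> Counter:
    """Pool per-replicate tracks, keeping positions covered in enough replicates.

    A position survives iff it has a nonzero count in at least
    *support_min_replicates* replicates; its pooled count is the plain sum of
    raw counts (no TPM or depth normalisation).  ``n_replicates`` is the
    total number of replicates supplied to the pipeline; fewer than
    *support_min_replicates* is a configuration error.
    """
    if n_replicates < support_min_replicates:
        raise ValueError(
            f"support_min_replicates={support_min_replicates} exceeds the "
            f"number of replicates ({n_replicates})")
    support: Counter = Counter()
    pooled: Counter = Counter()
    for counts in rep_tracks.values():
        for pos, c in counts.items():
            if c > 0:
                support[pos] += 1
                pooled[pos] += c
    return Counter({pos: pooled[pos] for pos, s in support.items()
                    if s >= support_min_replicates})


def call_clusters(pooled: Counter, chrom: str, strand: str, end_type: str,
                  pooled_cutoff: int = 2, merge_dist: int = 10,
                  rep_tracks: dict[str, Counter] | None = None,
                  strict: bool = True) -> list[EndPeak]:
    """Unidirectional clustering of a pooled end track into peaks.

    Candidate positions have pooled count > *pooled_cutoff* (>= when
    ``strict=False``).  Scanning left to right, two consecutive candidates
    join one cluster when the number of intervening non-candidate positions
    is smaller than *merge_dist*.  Each cluster becomes a peak spanning
    [first candidate, last candidate + 1) whose pooled count sums its
    candidate positions, with the summit at the maximal pooled count (ties
    break to the transcription-direction 5'-most candidate: smallest
    coordinate on "+", largest on "-").  Per-replicate counts sum the raw
    replicate counts over candidate positions when *rep_tracks* is given.
    """
    if strict:
        candidates = sorted(p for p, c in pooled.items() if c > pooled_cutoff)
    else:
        candidates = sorted(p for p, c in pooled.items() if c >= pooled_cutoff)
    peaks: list[EndPeak] = []
    cluster: list[int] = []
    for pos in candidates:
        if cluster and (pos - cluster[-1] - 1) >= merge_dist:
            peaks.append(_make_peak(cluster, pooled, chrom, strand, end_type,
                                    rep_tracks))
            cluster = []
        cluster.append(pos)
    if cluster:
        peaks.append(_make_peak(cluster, pooled, chrom, strand, end_type,
                                rep_tracks))
    return peaks


def _make_peak(cluster: list[int], pooled: Counter, chrom: str, strand: str,
               end_type: str, rep_tracks: dict[str, Counter] | None) -> EndPeak:
    region = GenomicInterval(chrom, cluster[0], cluster[-1] + 1, strand)
    best = max(pooled[p] for p in cluster)
    tied = [p for p in cluster if pooled[p] == best]
    summit = min(tied) if strand == "+" else max(tied)
    per_rep = {}
    if rep_tracks is not None:
        for rep, counts in rep_tracks.items():
            per_rep[rep] = sum(counts.get(p, 0) for p in cluster)
    peak_id = f"{'T' if end_type == FIVE_PRIME else 'P'}:{chrom}:{strand}:" \
              f"{region.start}-{region.end}"
    return EndPeak(peak_id, region, end_type, summit,
                   sum(pooled[p] for p in cluster), per_rep)


def call_all_peaks(reads_by_replicate: dict[str, Sequence[AlignedRead]],
                   support_min_replicates: int = 2, pooled_cutoff: int = 2,
                   merge_dist: int = 10, strict: bool = True
                   ) -> dict[TrackKey, list[EndPeak]]:
    """End-to-end peak calling: tracks -> support filter -> clusters.

    Peaks are called independently for every (chrom, strand, end type)
    track.
    """
    n_replicates = len(reads_by_replicate)
    tracks = build_end_tracks(reads_by_replicate)
    peaks: dict[TrackKey, list[EndPeak]] = {}
    for key in sorted(tracks):
        chrom, strand, end_type = key
        pooled = pool_with_support(tracks[key], n_replicates,
                                   support_min_replicates)
        peaks[key] = call_clusters(pooled, chrom, strand, end_type,
                                   pooled_cutoff, merge_dist,
                                   rep_tracks=tracks[key], strict=strict)
    n5 = sum(len(v) for k, v in peaks.items() if k[2] == FIVE_PRIME)
    n3 = sum(len(v) for k, v in peaks.items() if k[2] == THREE_PRIME)
    log.info("peak calling: %d TSS peaks, %d PA peaks", n5, n3)
    return peaks


class PeakIndex:
    """Point-in-peak lookup over disjoint peaks of one (chrom, strand, end type)."""

    def __init__(self, peaks_by_key: dict[TrackKey, list[EndPeak]], end_type: str):
        import bisect
        self._bisect = bisect
        self._index: dict[tuple[str, str], tuple[list[int], list[EndPeak]]] = {}
        for (chrom, strand, et), peaks in peaks_by_key.items():
            if et != end_type:
                continue
            ordered = sorted(peaks, key=lambda p: p.region.start)
            self._index[(chrom, strand)] = (
                [p.region.start for p in ordered], ordered)

    def find(self, chrom: str, strand: str, pos: int) -> EndPeak | None:
        entry = self._index.get((chrom, strand))
        if entry is None:
            return None
        starts, peaks = entry
        i = self._bisect.bisect_right(starts, pos) - 1
        if i >= 0 and peaks[i].region.contains(pos):
            return peaks[i]
        return None
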