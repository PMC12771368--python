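"""Splice-site identification and correction.

Candidate introns are the long ``N`` gaps of splice-aware alignments.  Because
long-read alignment is imprecise near junctions, each gap can be corrected
against a reference junction set (built from short-read junction tables or an
annotation): a gap whose two boundaries both lie within a tolerance of the
same reference intron is snapped to it; an unmatched gap is treated as a
deletion and removed from the read's chain.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .io import AnnotationTranscript

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def extract_introns(cigar: str, pos: int, chrom: str = "",
                    strand: str = "+") -> list[GenomicInterval]:
    """Intervals of the ``N`` operations of *cigar*, 0-based half-open.

    ``pos`` is the 0-based reference start of the alignment.  M/D/N/=/X
    advance the reference cursor; I/S/H/P do not.  A malformed CIGAR raises
    ``ValueError`` quoting it.
    """
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar or not cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    introns = []
    cursor = pos
    for length_s, op in ops:
        length = int(length_s)
        if op == "N":
            introns.append(GenomicInterval(chrom or "?", cursor,
                                           cursor + length, strand))
        if op in _REF_CONSUMING:
            cursor += length
    return introns


def reference_span(cigar: str, pos: int) -> tuple[int, int]:
    """Reference interval [start, end) consumed by *cigar* starting at *pos*."""
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar or not cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    end = pos + sum(int(n) for n, op in ops if op in _REF_CONSUMING)
    return pos, end


@dataclass
class JunctionSet:
    """Reference splice junctions indexed for tolerance lookups.

    Introns seen in fewer than ``min_samples`` distinct source samples are
    discarded at construction.  The index is a per-chromosome list of introns
    sorted by donor (start) coordinate; ``query`` returns every intron whose
    donor is within ``tolerance`` of a position, optionally filtered by
    acceptor distance and strand.
    """

    min_samples: int = 2
    # chrom -> parallel sorted lists (starts, (start, end, strand, support))
    _starts: dict[str, list[int]] = field(default_factory=dict)
    _introns: dict[str, list[tuple[int, int, str, int]]] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame, min_samples: int = 2) -> "JunctionSet":
        """Build from a (chrom, start, end, strand, sample) table.

        Support is the number of *distinct* samples containing the intron
        (duplicates within a sample count once); strand disagreements
        collapse to "undefined".
        """
        js = cls(min_samples=min_samples)
        if len(table) == 0:
            return js
        grouped = table.groupby(["chrom", "start", "end"], sort=True)
        for (chrom, start, end), grp in grouped:
            support = grp["sample"].nunique()
            if support < min_samples:
                continue
            strands = set(grp["strand"])
            strand = strands.pop() if len(strands) == 1 else "undefined"
            js._introns.setdefault(chrom, []).append(
                (int(start), int(end), strand, int(support)))
        for chrom, lst in js._introns.items():
            lst.sort()
            js._starts[chrom] = [s for s, *_ in lst]
        return js

    @classmethod
    def from_annotation(cls, transcripts: Iterable[AnnotationTranscript]) -> "JunctionSet":
        """Derive junctions from a GTF's implied introns.

        The annotation is treated as a single source sample that always
        passes the support rule.
        """
        rows = []
        for tx in transcripts:
            for intron in tx.introns:
                rows.append((intron.chrom, intron.start, intron.end,
                             intron.strand, "annotation"))
        table = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                            "strand", "sample"])
        return cls.from_table(table, min_samples=1)

    def __len__(self) -> int:
        return sum(len(v) for v in self._introns.values())

    def __iter__(self):
        for chrom in sorted(self._introns):
            for start, end, strand, support in self._introns[chrom]:
                yield chrom, start, end, strand, support

    def query(self, chrom: str, start: int, end: int, tolerance: int,
              strand: str | None = None) -> list[tuple[int, int, str]]:
        """Introns with |donor - start| <= t and |acceptor - end| <= t.

        If *strand* is given, introns must match it or be strand-undefined.
        """
        starts = self._starts.get(chrom)
        if not starts:
            return []
        lo = bisect.bisect_left(starts, start - tolerance)
        hi = bisect.bisect_right(starts, start + tolerance)
        out = []
        for s, e, st, _support in self._introns[chrom][lo:hi]:
            if abs(e - end) > tolerance:
                continue
            if strand is not None and st != "undefined" and st != strand:
                continue
            out.append((s, e, st))
        return out


def correct_introns(chain: Sequence[GenomicInterval], ref: JunctionSet,
                    tolerance: int, strand_aware: bool = False,
                    ) -> tuple[list[GenomicInterval], dict[str, int]]:
    """Correct an intron chain against a junction reference.

    Per gap, independently: among reference introns on the gap's chromosome
    with both boundary displacements <= *tolerance*, the one minimising
    |d-donor| + |d-acceptor| replaces the gap (ties: smaller donor, then
    smaller acceptor); with no admissible candidate the gap is removed from
    the chain.  Afterwards the chain is re-checked for sortedness and
    non-overlap; a replacement overlapping its predecessor is dropped with a
    logged warning.

    Returns the corrected chain and a stats dict with keys ``exact``,
    ``corrected``, ``removed``, ``overlap_dropped``.
    """
    stats = {"exact": 0, "corrected": 0, "removed": 0, "overlap_dropped": 0}
    replaced: list[GenomicInterval] = []
    for gap in chain:
        cands = ref.query(gap.chrom, gap.start, gap.end, tolerance,
                          strand=gap.strand if strand_aware else None)
        if not cands:
            stats["removed"] += 1
            continue
        best = min(cands, key=lambda c: (abs(c[0] - gap.start) + abs(c[1] - gap.end),
                                         c[0], c[1]))
        if (best[0], best[1]) == (gap.start, gap.end):
            stats["exact"] += 1
            replaced.append(gap)
        else:
            stats["corrected"] += 1
            replaced.append(GenomicInterval(gap.chrom, best[0], best[1], gap.strand))
    out: list[GenomicInterval] = []
    for intron in sorted(replaced, key=lambda g: (g.start, g.end)):
        if out and intron.start < out[-1].end:
            stats["overlap_dropped"] += 1
            log.warning("corrected intron [%d,%d) overlaps predecessor; dropped",
                        intron.start, intron.end)
            continue
        out.append(intron)
    return out, stats


def correct_read_introns(reads, ref: JunctionSet, tolerance: int,
                         strand_aware: bool = False) -> dict[str, int]:
    """Correct every read's chain in place; returns aggregate stats."""
    total = {"exact": 0, "corrected": 0, "removed": 0, "overlap_dropped": 0}
    for read in reads:
        read.introns, stats = correct_introns(read.introns, ref, tolerance,
                                              strand_aware=strand_aware)
        for k, v in stats.items():
            total[k] += v
    log.info("splice correction: %s", total)
    return total


def fill_read_introns(reads) -> None:
    """Populate each read's intron chain from its CIGAR string."""
    for read in reads:
        read.introns = extract_introns(read.cigar, read.location.start,
                                       read.location.chrom, read.location.strand)
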