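"""Genomic interval primitives.

All internal coordinates are 0-based half-open ``[start, end)``; conversion to
the 1-based inclusive convention of GTF and STAR ``SJ.out.tab`` happens only at
format boundaries (see :mod:`isopeak.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start : int
        0-based inclusive start, ``0 <= start < end``.
    end : int
        0-based exclusive end.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, start: int | None = None, end: int | None = None) -> "GenomicInterval":
        """Copy with one or both boundaries replaced."""
        return GenomicInterval(
            self.chrom,
            self.start if start is None else start,
            self.end if end is None else end,
            self.strand,
        )


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GTF/SJ convention)."""
    return start + 1, end


def to_zero_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last
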