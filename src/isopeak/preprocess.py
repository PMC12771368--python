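"""Read-level preprocessing.

Whole-read mean-quality filtering (ONT pass/fail convention, mean taken in
error-probability space), poly(A) tail trimming with cutadapt-style 3'-adapter
semantics, a contract wrapper around the external splice-aware aligner, and
the unique-alignment filter that keeps only reads with a single linear
placement.
"""

from __future__ import annotations

import logging
import math
import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .intervals import GenomicInterval
from .io import AlignmentRecord

log = logging.getLogger(__name__)


@dataclass
class AlignedRead:
    """One uniquely mapped long read — the atomic evidence unit.

    ``introns`` starts out empty and is filled by the splice module from the
    CIGAR string (and optionally corrected against a junction reference).
    """

    read_id: str
    replicate: str
    location: GenomicInterval
    introns: list[GenomicInterval] = field(default_factory=list)
    primary_count: int = 1
    cigar: str = ""

    @property
    def five_prime(self) -> int:
        """5' end position (reads are in mRNA sense by the input contract)."""
        loc = self.location
        return loc.start if loc.strand == "+" else loc.end - 1

    @property
    def three_prime(self) -> int:
        loc = self.location
        return loc.end - 1 if loc.strand == "+" else loc.start


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def mean_phred(qualities: Sequence[int]) -> float:
    """Mean quality of a read: -10*log10 of the mean per-base error probability."""
    if not qualities:
        return 0.0
    mean_p = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
    return -10.0 * math.log10(mean_p)


def filter_by_quality(records: Iterable, quality_min: float) -> Iterator:
    """Yield FASTQ records whose mean-probability Phred is >= *quality_min*.

    ``records`` are Bio.SeqIO SeqRecords with ``phred_quality`` annotations.
    Dropped reads are counted and reported at INFO level.
    """
    kept = dropped = 0
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise ValueError(f"read {rec.id}: quality/sequence length mismatch")
        if mean_phred(quals) >= quality_min:
            kept += 1
            yield rec
        else:
            dropped += 1
    log.info("quality filter: kept %d, dropped %d reads", kept, dropped)


# ---------------------------------------------------------------------------
# Poly(A) trimming
# ---------------------------------------------------------------------------

def trim_polya(sequence: str, adapter_len: int = 100,
               error_rate: float = 0.1, min_overlap: int = 3) -> str:
    """Remove a 3' poly(A) tail (and anything 3' of it) from *sequence*.

    3'-adapter semantics for the adapter ``A * adapter_len``: the best
    semi-global match is a window starting at position ``i`` and running to
    the 3' end (capped at ``adapter_len`` bases — a full internal adapter
    occurrence removes the remainder of the read as well), admissible when
    its mismatch count divided by its length is <= *error_rate* and its
    length is >= *min_overlap*.  Among admissible matches the best-scoring
    one (matches minus mismatches, ties to the longer match) is removed.
    Trimming is repeated until no admissible match remains so the operation
    is idempotent.
    """
    seq = sequence
    while True:
        cut = _polya_cut(seq, adapter_len, error_rate, min_overlap)
        if cut is None:
            return seq
        seq = seq[:cut]


def _polya_cut(seq: str, adapter_len: int, error_rate: float,
               min_overlap: int) -> int | None:
    n = len(seq)
    best: tuple[int, int] | None = None  # (score, -i)
    best_i = None
    for i in range(0, n - min_overlap + 1):
        window = seq[i:i + adapter_len]
        errors = sum(1 for c in window if c not in "Aa")
        if errors > error_rate * len(window):
            continue
        score = len(window) - 2 * errors
        key = (score, -i)
        if best is None or key > best:
            best, best_i = key, i
    return best_i


# ---------------------------------------------------------------------------
# Alignment (shell-out)
# ---------------------------------------------------------------------------

def align_reads(fastq_paths: Sequence[str | Path], genome: str | Path,
                out_sam: str | Path, aligner_args: str = "-ax splice -k14 -uf -G 10k",
                executable: str = "minimap2", threads: int = 1) -> Path:
    """Run the external splice-aware aligner; arguments pass through verbatim.

    Returns the SAM path.  A missing executable or nonzero exit raises
    ``RuntimeError`` carrying the captured stderr.
    """
    if shutil.which(executable) is None:
        raise RuntimeError(f"aligner executable {executable!r} not found on PATH")
    cmd = [executable, *shlex.split(aligner_args), "-t", str(threads),
           str(genome), *map(str, fastq_paths)]
    with open(out_sam, "w") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"{executable} exited with status {proc.returncode}:\n{proc.stderr}")
    return Path(out_sam)


# ---------------------------------------------------------------------------
# Unique-alignment filter
# ---------------------------------------------------------------------------

def unique_alignment_filter(records: Iterable[AlignmentRecord]) -> list[AlignedRead]:
    """Keep reads with exactly one linear placement.

    A read is retained iff it produced exactly one alignment record counting
    primaries and supplementaries together, and no secondary records.  This
    drops multi-mappers and split/chimeric placements (supplementary-bearing
    reads), the artifact class long-read cDNA is prone to.
    """
    n_records = 0
    primary: dict[str, AlignmentRecord] = {}
    placements: dict[str, int] = {}
    secondaries: set[str] = set()
    for rec in records:
        n_records += 1
        if rec.is_unmapped:
            placements.setdefault(rec.read_id, 0)
            continue
        if rec.is_secondary:
            secondaries.add(rec.read_id)
            placements.setdefault(rec.read_id, 0)
            continue
        placements[rec.read_id] = placements.get(rec.read_id, 0) + 1
        if not rec.is_supplementary:
            primary[rec.read_id] = rec

    out = []
    for read_id, n in placements.items():
        if n != 1 or read_id in secondaries or read_id not in primary:
            continue
        rec = primary[read_id]
        out.append(AlignedRead(
            read_id=read_id,
            replicate=rec.replicate,
            location=GenomicInterval(rec.chrom, rec.start, rec.end, rec.strand),
            primary_count=1,
            cigar=rec.cigar,
        ))
    out.sort(key=lambda r: (r.location.chrom, r.location.start, r.read_id))
    log.info("unique-alignment filter: %d records -> %d uniquely mapped reads",
             n_records, len(out))
    return out


def read_fastq(path: str | Path) -> Iterator:
    return SeqIO.parse(str(path), "fastq")


def write_fastq(records: Iterable, path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fastq")
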