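import random

import pandas as pd
import pytest

from isopeak.intervals import GenomicInterval
from isopeak.io import AnnotationTranscript
from isopeak.splice import (JunctionSet, correct_introns, extract_introns,
                            reference_span)


def _iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestExtractIntrons:
    @pytest.mark.parametrize("cigar,pos,expected", [
        ("10M100N10M", 10, [(20, 120)]),
        ("5S10M50N20M3S", 100, [(110, 160)]),
        ("30M", 0, []),
        ("10M5I10M40N10M5D10M60N5M", 0, [(20, 60), (85, 145)]),
    ])
    def test_cigar_walk(self, cigar, pos, expected):
        out = extract_introns(cigar, pos, "chr1", "+")
        assert [(i.start, i.end) for i in out] == expected

    def test_malformed_cigar_quoted(self):
        with pytest.raises(ValueError, match="10M3Q"):
            extract_introns("10M3Q", 0)
        with pytest.raises(ValueError):
            extract_introns("", 0)

    def test_reference_length_conservation(self):
        """Sum of M/D/N/=/X lengths equals the reference span length."""
        rng = random.Random(5)
        for _ in range(200):
            parts, ref_len = [], 0
            for _ in range(rng.randint(1, 10)):
                op = rng.choice("MIDNS=X")
                n = rng.randint(1, 50)
                parts.append(f"{n}{op}")
                if op in "MDN=X":
                    ref_len += n
            cigar = "".join(parts)
            pos = rng.randint(0, 1000)
            start, end = reference_span(cigar, pos)
            assert end - start == ref_len
            for intron in extract_introns(cigar, pos):
                assert start <= intron.start < intron.end <= end


def _table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "sample"])


class TestJunctionReference:
    def test_two_sample_rule(self):
        table = _table([("chr1", 100, 200, "+", "A"),
                        ("chr1", 100, 200, "+", "B"),     # J: 2 samples
                        ("chr1", 300, 400, "+", "A"),     # K: 1 sample
                        ("chr1", 500, 600, "+", "A"),
                        ("chr1", 500, 600, "+", "A")])    # L: dup in 1 sample
        js = JunctionSet.from_table(table, min_samples=2)
        stored = {(c, s, e) for c, s, e, *_ in js}
        assert stored == {("chr1", 100, 200)}

    def test_annotation_counts_as_one_passing_sample(self):
        tx = AnnotationTranscript("t1", "g1", _iv(0, 300),
                                  [_iv(0, 100), _iv(200, 300)])
        js = JunctionSet.from_annotation([tx])
        assert {(s, e) for _, s, e, *_ in js} == {(100, 200)}

    def test_index_matches_linear_scan(self):
        """Tolerance lookups agree with a brute-force scan (random sets)."""
        rng = random.Random(42)
        introns = sorted({(rng.randrange(0, 3000), rng.randrange(40, 300))
                          for _ in range(300)})
        rows = []
        for s, l in introns:
            rows.append(("chr1", s, s + l, "+", "A"))
            rows.append(("chr1", s, s + l, "+", "B"))
        js = JunctionSet.from_table(_table(rows), min_samples=2)
        stored = [(s, e) for _, s, e, *_ in js]
        for _ in range(10_000):
            q_start = rng.randrange(-20, 3100)
            q_end = q_start + rng.randrange(30, 320)
            tol = rng.choice([0, 1, 5, 10, 25])
            got = sorted((s, e) for s, e, _ in
                         js.query("chr1", q_start, q_end, tol))
            expected = sorted((s, e) for s, e in stored
                              if abs(s - q_start) <= tol and abs(e - q_end) <= tol)
            assert got == expected


class TestCorrectIntrons:
    def _ref(self, introns, strand="+"):
        rows = [("chr1", s, e, strand, smp)
                for s, e in introns for smp in ("A", "B")]
        return JunctionSet.from_table(_table(rows), min_samples=2)

    def test_replacement_within_tolerance(self):
        ref = self._ref([(1005, 1095)])
        out, stats = correct_introns([_iv(1000, 1100)], ref, 10)
        assert [(i.start, i.end) for i in out] == [(1005, 1095)]
        assert stats["corrected"] == 1

    def test_exact_match_unchanged(self):
        ref = self._ref([(1000, 1100)])
        out, stats = correct_introns([_iv(1000, 1100)], ref, 10)
        assert [(i.start, i.end) for i in out] == [(1000, 1100)]
        assert stats["exact"] == 1

    def test_gap_removed_when_no_candidate(self):
        """Donor 20 bp off: no admissible candidate, gap deleted."""
        ref = self._ref([(1020, 1095)])
        out, stats = correct_introns([_iv(1000, 1100)], ref, 10)
        assert out == [] and stats["removed"] == 1

    def test_empty_reference_removes_every_gap(self):
        ref = JunctionSet.from_table(_table([]), min_samples=2)
        chain = [_iv(100, 200), _iv(300, 400)]
        out, stats = correct_introns(chain, ref, 10)
        assert out == [] and stats["removed"] == 2

    def test_minimal_total_displacement_wins(self):
        ref = self._ref([(995, 1101), (1003, 1102)])
        out, _ = correct_introns([_iv(1000, 1100)], ref, 10)
        # displacements: 5+1=6 vs 3+2=5 -> second intron wins
        assert [(i.start, i.end) for i in out] == [(1003, 1102)]

    def test_boundary_displacement_bounded(self):
        rng = random.Random(9)
        introns = [(i * 500, i * 500 + rng.randrange(60, 200))
                   for i in range(1, 40)]
        ref = self._ref(introns)
        for _ in range(500):
            s, e = rng.choice(introns)
            gap = _iv(s + rng.randrange(-15, 16),
                      e + rng.randrange(-15, 16))
            out, _ = correct_introns([gap], ref, 10)
            for intron in out:
                assert abs(intron.start - gap.start) <= 10
                assert abs(intron.end - gap.end) <= 10

    def test_overlapping_replacement_dropped(self):
        ref = self._ref([(100, 210), (205, 300)])
        out, stats = correct_introns([_iv(100, 205), _iv(208, 300)], ref, 10)
        starts_ends = [(i.start, i.end) for i in out]
        assert starts_ends == [(100, 210)]
        assert stats["overlap_dropped"] == 1

    def test_strand_aware_toggle(self):
        rows = [("chr1", 100, 200, "-", s) for s in ("A", "B")]
        ref = JunctionSet.from_table(_table(rows), min_samples=2)
        out, _ = correct_introns([_iv(100, 200, strand="+")], ref, 10)
        assert len(out) == 1          # coordinate-only matching by default
        out, _ = correct_introns([_iv(100, 200, strand="+")], ref, 10,
                                 strand_aware=True)
        assert out == []
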