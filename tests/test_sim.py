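import numpy as np
import pytest

from isopeak.intervals import GenomicInterval
from isopeak.io import AnnotationTranscript, isoform_sequence
from isopeak.sim import (DISTORTION_CASES, SimConfig, distort_annotation,
                         make_toy_genome, simulate_reads, write_fixture,
                         _one_read)
from conftest import clean_sim_config


class TestToyGenome:
    def test_structural_contract(self):
        sim = SimConfig(seed=3, n_genes=1, n_chroms=1,
                        isoforms_per_gene=(1, 1), exons_per_isoform=(2, 2))
        genome, txs = make_toy_genome(sim)
        assert len(txs) == 1 and len(txs[0].exons) == 2
        intron = txs[0].introns[0]
        seq = genome[intron.chrom]
        if txs[0].location.strand == "+":
            assert seq[intron.start:intron.start + 2] == "GT"
            assert seq[intron.end - 2:intron.end] == "AG"
        else:
            assert seq[intron.start:intron.start + 2] == "CT"
            assert seq[intron.end - 2:intron.end] == "AC"

    def test_determinism(self):
        sim = SimConfig(seed=5, n_genes=6)
        g1, t1 = make_toy_genome(sim)
        g2, t2 = make_toy_genome(SimConfig(seed=5, n_genes=6))
        assert g1 == g2
        assert [(t.transcript_id, t.location) for t in t1] == \
            [(t.transcript_id, t.location) for t in t2]

    def test_gene_spans_disjoint(self):
        sim = SimConfig(seed=7, n_genes=20, n_chroms=2)
        _, txs = make_toy_genome(sim)
        by_chrom = {}
        for tx in txs:
            by_chrom.setdefault((tx.gene_id, tx.location.chrom), []).append(tx)
        spans = {}
        for (gid, chrom), group in by_chrom.items():
            spans.setdefault(chrom, []).append(
                (min(t.location.start for t in group),
                 max(t.location.end for t in group)))
        for chrom, intervals in spans.items():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_too_many_genes_is_sizing_error(self):
        with pytest.raises(ValueError, match="fit"):
            make_toy_genome(SimConfig(seed=1, n_genes=100, n_chroms=1,
                                      chrom_len=20_000))


class TestReadSimulation:
    def test_clean_limit_reproduces_exon_chain(self, clean_sim):
        """Zero error rates, completeness 1, jitter 0: every read's truth
        alignment equals the transcript's exact exon chain."""
        _, genome, transcripts, data = clean_sim
        tx_by_id = {t.transcript_id: t for t in transcripts}
        for reads in data.reads_by_replicate.values():
            for read in reads:
                tx = tx_by_id[read.transcript_id]
                assert read.blocks == [(e.start, e.end) for e in tx.exons]
                assert read.clean_seq == isoform_sequence(tx, genome)

    def test_half_completeness_shifts_truth_alignment(self):
        """completeness_5p = 0.5 drops the 5' half; the truth alignment
        starts midway through the transcript."""
        chrom = "chr1"
        loc = GenomicInterval(chrom, 100, 400, "+")
        tx = AnnotationTranscript("t", "g", loc,
                                  [GenomicInterval(chrom, 100, 200, "+"),
                                   GenomicInterval(chrom, 300, 400, "+")])
        sim = SimConfig(completeness_5p=0.5, completeness_3p=1.0,
                        end_jitter_sd=0.0, subst_rate=0.0, indel_rate=0.0)
        rng = np.random.default_rng(0)
        read = _one_read(rng, sim, tx, "A" * 200, "rep1", 0)
        # transcript length 200; 5' cut at 100 -> second exon only
        assert read.blocks == [(300, 400)]

        minus = AnnotationTranscript(
            "t2", "g", GenomicInterval(chrom, 100, 400, "-"),
            [GenomicInterval(chrom, 100, 200, "-"),
             GenomicInterval(chrom, 300, 400, "-")])
        read = _one_read(rng, sim, minus, "A" * 200, "rep1", 0)
        # 5' of a minus transcript is the right end -> left exon remains
        assert read.blocks == [(100, 200)]

    def test_negative_binomial_expression_mean(self):
        """NB(n=1, p=0.004) has mean n(1-p)/p ~ 249; the empirical mean over
        500 isoforms is within 3 standard errors."""
        rng = np.random.default_rng(12)
        draws = rng.negative_binomial(1, 0.004, size=500)
        expected = 1 * (1 - 0.004) / 0.004
        se = np.sqrt(expected / 0.004) / np.sqrt(500)
        assert abs(draws.mean() - expected) < 3 * se

    def test_polya_and_errors_present_in_fastq(self):
        sim = clean_sim_config(seed=2, reads=3, subst_rate=0.0,
                               polya_len=(25, 25))
        genome, txs = make_toy_genome(sim)
        data = simulate_reads(genome, txs, sim)
        for read in data.reads_by_replicate["rep1"]:
            assert read.fastq_seq.endswith("A" * 25)
            assert read.fastq_seq[:-25] == read.clean_seq

    def test_fixture_write_determinism(self, tmp_path):
        sim = clean_sim_config(seed=6, reads=5, n_genes=4)
        genome, txs = make_toy_genome(sim)
        data = simulate_reads(genome, txs, sim)
        p1 = write_fixture(data, tmp_path / "a")
        p2 = write_fixture(data, tmp_path / "b")
        for key in ("genome", "annotation"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
        for rep in p1["truth_sam"]:
            assert p1["truth_sam"][rep].read_bytes() == \
                p2["truth_sam"][rep].read_bytes()


class TestDistortAnnotation:
    def _tx(self, start, end, strand, exons=None):
        loc = GenomicInterval("chr1", start, end, strand)
        exons = exons or [loc]
        return AnnotationTranscript("t", "g", loc, list(exons))

    def _case(self, tx, case, shift=100):
        from isopeak.sim import _apply_distortion
        return _apply_distortion(tx, case, shift)

    def test_plus_five_upstream(self):
        out = self._case(self._tx(1000, 2000, "+"), "five_upstream")
        assert (out.location.start, out.location.end) == (900, 2000)

    def test_minus_five_upstream(self):
        out = self._case(self._tx(1000, 2000, "-"), "five_upstream")
        assert (out.location.start, out.location.end) == (1000, 2100)

    def test_no_change(self):
        out = self._case(self._tx(1000, 2000, "+"), "none")
        assert (out.location.start, out.location.end) == (1000, 2000)

    def test_both_downstream_strand_aware(self):
        plus = self._case(self._tx(1000, 2000, "+"), "both_downstream")
        assert (plus.location.start, plus.location.end) == (1100, 2100)
        minus = self._case(self._tx(1000, 2000, "-"), "both_downstream")
        assert (minus.location.start, minus.location.end) == (900, 1900)

    def test_shift_truncates_short_of_junction(self):
        """An inward shift crossing the first junction stops 1 bp short."""
        tx = self._tx(1000, 2000, "+",
                      [GenomicInterval("chr1", 1000, 1050, "+"),
                       GenomicInterval("chr1", 1500, 2000, "+")])
        out = self._case(tx, "five_downstream")
        assert out.exons[0].start == 1049
        assert out.exons[0].end == 1050          # junction untouched

    def test_internal_splice_sites_untouched(self):
        tx = self._tx(1000, 2000, "+",
                      [GenomicInterval("chr1", 1000, 1200, "+"),
                       GenomicInterval("chr1", 1500, 2000, "+")])
        out = self._case(tx, "both_upstream")
        assert [(i.start, i.end) for i in out.introns] == [(1200, 1500)]

    def test_distribution_uniform(self):
        """7000 transcripts: each case within 3 sigma of 1000."""
        txs = [self._tx(i * 10_000, i * 10_000 + 500, "+") for i in range(7000)]
        _, labels = distort_annotation(txs, seed=123)
        from collections import Counter
        counts = Counter(labels)
        sigma = np.sqrt(7000 * (1 / 7) * (6 / 7))
        for case in DISTORTION_CASES:
            assert abs(counts[case] - 1000) < 3 * sigma
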