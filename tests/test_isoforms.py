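import random

import pytest

from isopeak.end_peaks import (FIVE_PRIME, THREE_PRIME, EndPeak, PeakIndex)
from isopeak.intervals import GenomicInterval
from isopeak.io import AnnotationTranscript
from isopeak.isoforms import (IsoformCandidate, IsoformModel, GeneModel,
                              assign_ends, assign_gene_ids, build_exons,
                              build_isoforms, candidate_span, cluster_genes,
                              filter_by_replicates, filter_minor_isoforms,
                              group_reads, spans_linked)
from isopeak.preprocess import AlignedRead


def _peak(start, end, summit, end_type, strand="+", chrom="chr1"):
    return EndPeak(f"{end_type[:1]}:{chrom}:{strand}:{start}-{end}",
                   GenomicInterval(chrom, start, end, strand), end_type,
                   summit, 10)


def _index(peaks, end_type, strand="+"):
    return PeakIndex({("chr1", strand, end_type): peaks}, end_type)


def _read(start, end, strand="+", rid="r1", rep="rep1", introns=()):
    read = AlignedRead(rid, rep, GenomicInterval("chr1", start, end, strand))
    read.introns = [GenomicInterval("chr1", s, e, strand) for s, e in introns]
    return read


class TestAssignEnds:
    def test_both_ends_inside(self):
        tss = _index([_peak(100, 110, 105, FIVE_PRIME)], FIVE_PRIME)
        pa = _index([_peak(495, 505, 500, THREE_PRIME)], THREE_PRIME)
        got = assign_ends(_read(105, 500), tss, pa)
        assert got[0].region.start == 100 and got[1].region.start == 495

    def test_five_prime_outside_rejected(self):
        tss = _index([_peak(100, 110, 105, FIVE_PRIME)], FIVE_PRIME)
        pa = _index([_peak(495, 505, 500, THREE_PRIME)], THREE_PRIME)
        assert assign_ends(_read(95, 500), tss, pa) == "no_tss"
        assert assign_ends(_read(105, 520), tss, pa) == "no_pa"

    def test_minus_strand_bookkeeping(self):
        """A - read [100,200): 5' position 199 is looked up on the - strand
        five_prime track."""
        tss = _index([_peak(195, 205, 199, FIVE_PRIME, "-")], FIVE_PRIME, "-")
        pa = _index([_peak(95, 105, 100, THREE_PRIME, "-")], THREE_PRIME, "-")
        got = assign_ends(_read(100, 200, "-"), tss, pa)
        assert got[0].end_type == FIVE_PRIME and got[0].summit == 199


class TestGrouping:
    def _indices(self):
        tss = _index([_peak(100, 110, 100, FIVE_PRIME),
                      _peak(130, 140, 130, FIVE_PRIME)], FIVE_PRIME)
        pa = _index([_peak(495, 505, 500, THREE_PRIME)], THREE_PRIME)
        return tss, pa

    def test_identical_key_groups(self):
        tss, pa = self._indices()
        reads = [_read(105, 500, rid="a", introns=[(200, 300)]),
                 _read(103, 499, rid="b", introns=[(200, 300)])]
        cands, rejects = group_reads(reads, tss, pa)
        assert len(cands) == 1 and cands[0].counts == {"rep1": 2}
        assert rejects == []

    def test_one_bp_chain_difference_splits(self):
        tss, pa = self._indices()
        reads = [_read(105, 500, rid="a", introns=[(200, 300)]),
                 _read(105, 500, rid="b", introns=[(201, 300)])]
        cands, _ = group_reads(reads, tss, pa)
        assert len(cands) == 2

    def test_different_tss_peak_splits(self):
        tss, pa = self._indices()
        reads = [_read(105, 500, rid="a", introns=[(200, 300)]),
                 _read(132, 500, rid="b", introns=[(200, 300)])]
        cands, _ = group_reads(reads, tss, pa)
        assert len(cands) == 2

    def test_conservation(self):
        """assigned + rejected == input reads."""
        tss, pa = self._indices()
        reads = [_read(105, 500, rid="a"), _read(10, 500, rid="b"),
                 _read(105, 900, rid="c")]
        cands, rejects = group_reads(reads, tss, pa)
        assert sum(sum(c.counts.values()) for c in cands) + len(rejects) == 3
        assert sorted(r for _, r in rejects) == ["no_pa", "no_tss"]


def _cand(counts):
    return IsoformCandidate(_peak(100, 110, 100, FIVE_PRIME),
                            _peak(495, 505, 500, THREE_PRIME),
                            (), counts, "chr1", "+")


class TestReplicateFilter:
    @pytest.mark.parametrize("counts,kept", [
        ({"r1": 6, "r2": 1, "r3": 0}, True),
        ({"r1": 5, "r2": 0, "r3": 0}, False),
        ({"r1": 4, "r2": 4, "r3": 4}, False),
        ({"r1": 5, "r2": 1}, True),
        ({"r1": 1, "r2": 5}, True),
    ])
    def test_high_low_rule(self, counts, kept):
        out = filter_by_replicates([_cand(counts)], 5, 1)
        assert bool(out) is kept

    def test_zero_threshold_still_needs_second_replicate(self):
        assert filter_by_replicates([_cand({"r1": 3})], 0, 1) == []
        assert len(filter_by_replicates([_cand({"r1": 3, "r2": 1})], 0, 1)) == 1


class TestExonAssembly:
    def test_two_exon_assembly(self):
        cand = IsoformCandidate(_peak(95, 105, 100, FIVE_PRIME),
                                _peak(295, 305, 300, THREE_PRIME),
                                (GenomicInterval("chr1", 150, 250, "+"),),
                                {"r1": 5}, "chr1", "+")
        exons = build_exons(cand)
        assert [(e.start, e.end) for e in exons] == [(100, 150), (250, 301)]
        span = candidate_span(cand)
        assert (span.start, span.end) == (95, 305)

    def test_intronless(self):
        cand = IsoformCandidate(_peak(100, 101, 100, FIVE_PRIME),
                                _peak(200, 201, 200, THREE_PRIME),
                                (), {"r1": 5}, "chr1", "+")
        assert [(e.start, e.end) for e in build_exons(cand)] == [(100, 201)]

    def test_minus_strand_same_genomic_exons(self):
        cand = IsoformCandidate(
            _peak(295, 305, 300, FIVE_PRIME, "-"),
            _peak(95, 105, 100, THREE_PRIME, "-"),
            (GenomicInterval("chr1", 150, 250, "-"),),
            {"r1": 5}, "chr1", "-")
        exons = build_exons(cand)
        assert [(e.start, e.end) for e in exons] == [(100, 150), (250, 301)]

    def test_inconsistent_summit_dropped(self):
        """TSS summit 3' of the first intron start: dropped with a warning."""
        cand = IsoformCandidate(_peak(160, 170, 165, FIVE_PRIME),
                                _peak(295, 305, 300, THREE_PRIME),
                                (GenomicInterval("chr1", 150, 250, "+"),),
                                {"r1": 5}, "chr1", "+")
        assert build_exons(cand) is None
        assert build_isoforms([cand]) == []


def _iso(iid, start, end, strand="+", total=10):
    tss = _peak(start, start + 1, start, FIVE_PRIME, strand)
    pa = _peak(end - 1, end, end - 1, THREE_PRIME, strand)
    return IsoformModel(iid, tss, pa, (), {"r1": total},
                        GenomicInterval("chr1", start, end, strand),
                        [GenomicInterval("chr1", start, end, strand)])


class TestGeneClustering:
    def test_eighty_percent_rule_arithmetic(self):
        a, b = _iso("a", 0, 100), _iso("b", 10, 120)
        assert spans_linked(a.span, b.span, 0.8)       # overlap 90 >= 80
        c = _iso("c", 90, 200)
        assert not spans_linked(a.span, c.span, 0.8)   # overlap 10 < 80
        genes = cluster_genes([a, b, c], 0.8)
        assert sorted(len(g.isoforms) for g in genes) == [1, 2]

    def test_transitive_closure(self):
        a, b, c = _iso("a", 0, 100), _iso("b", 60, 160), _iso("c", 120, 220)
        genes = cluster_genes([a, b, c], 0.4)
        assert len(genes) == 1 and len(genes[0].isoforms) == 3
        assert (genes[0].span.start, genes[0].span.end) == (0, 220)

    def test_strand_separate(self):
        genes = cluster_genes([_iso("a", 0, 100), _iso("b", 0, 100, "-")], 0.8)
        assert len(genes) == 2

    def test_matches_connected_components_oracle(self):
        """Union-find clustering equals brute-force BFS components on random
        span sets."""
        rng = random.Random(3)
        for _ in range(100):
            isos = []
            for i in range(rng.randint(1, 40)):
                s = rng.randrange(0, 2000)
                isos.append(_iso(f"i{i}", s, s + rng.randrange(50, 400)))
            frac = rng.choice([0.5, 0.8, 1.0])
            genes = cluster_genes(isos, frac)
            got = sorted(sorted(i.isoform_id for i in g.isoforms)
                         for g in genes)
            # oracle: BFS over the explicit all-pairs relation
            adj = {i.isoform_id: set() for i in isos}
            for a in isos:
                for b in isos:
                    if a.isoform_id != b.isoform_id and \
                            spans_linked(a.span, b.span, frac):
                        adj[a.isoform_id].add(b.isoform_id)
            seen, comps = set(), []
            for iso in isos:
                if iso.isoform_id in seen:
                    continue
                comp, queue = [], [iso.isoform_id]
                seen.add(iso.isoform_id)
                while queue:
                    x = queue.pop()
                    comp.append(x)
                    for y in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            queue.append(y)
                comps.append(sorted(comp))
            assert got == sorted(comps)


class TestGeneNaming:
    def _ann(self, gene_id, start, end, strand="+"):
        loc = GenomicInterval("chr1", start, end, strand)
        return AnnotationTranscript(f"{gene_id}.t", gene_id, loc, [loc])

    def test_identity_named(self):
        genes = cluster_genes([_iso("a", 0, 1000)], 0.8)
        assign_gene_ids(genes, [self._ann("G1", 0, 1000)], 0.8)
        assert genes[0].gene_id == "G1"
        assert genes[0].isoforms[0].isoform_id == "G1.i1"

    def test_insufficient_overlap_gets_novel_id(self):
        genes = cluster_genes([_iso("a", 0, 1000)], 0.8)
        assign_gene_ids(genes, [self._ann("G2", 900, 2000)], 0.8)
        assert genes[0].gene_id.startswith("IPKG_chr1_0_")
        assert genes[0].annotation_id is None

    def test_larger_overlap_wins(self):
        genes = cluster_genes([_iso("a", 0, 1000)], 0.8)
        ann = [self._ann("GA", 0, 900), self._ann("GB", 0, 1000)]
        assign_gene_ids(genes, ann, 0.8)
        assert genes[0].gene_id == "GB"

    def test_strand_enforced(self):
        genes = cluster_genes([_iso("a", 0, 1000)], 0.8)
        assign_gene_ids(genes, [self._ann("G1", 0, 1000, "-")], 0.8)
        assert genes[0].gene_id.startswith("IPKG_")


class TestMinorIsoformFilter:
    def test_one_percent_boundary(self):
        """Major 1000: a minor with 11 reads is kept (11 > 10), 10 dropped."""
        gene = GeneModel("g", GenomicInterval("chr1", 0, 1000, "+"),
                         [_iso("maj", 0, 1000, total=1000),
                          _iso("k", 0, 1000, total=11),
                          _iso("d", 0, 1000, total=10)])
        out = filter_minor_isoforms(gene, 0.01)
        assert [i.isoform_id for i in out.isoforms] == ["maj", "k"]

    def test_tied_majors_all_kept(self):
        gene = GeneModel("g", GenomicInterval("chr1", 0, 1000, "+"),
                         [_iso("a", 0, 1000, total=50),
                          _iso("b", 0, 1000, total=50)])
        out = filter_minor_isoforms(gene, 0.01)
        assert len(out.isoforms) == 2

    def test_single_isoform_unchanged(self):
        gene = GeneModel("g", GenomicInterval("chr1", 0, 1000, "+"),
                         [_iso("a", 0, 1000, total=3)])
        assert len(filter_minor_isoforms(gene, 0.01).isoforms) == 1
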