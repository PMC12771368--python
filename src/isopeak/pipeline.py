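"""End-to-end reconstruction pipeline.

Orchestrates the stages: (optional) read quality filtering, poly(A) trimming
and splice-aware alignment; the unique-alignment filter; intron extraction
and (optional) splice correction; (optional) downsampling; end-peak calling;
isoform grouping and filtering; gene clustering, naming and output emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import downsample as ds
from . import end_peaks as ep
from . import isoforms as iso
from . import preprocess as pp
from . import splice
from .config import PipelineConfig
from .io import (AnnotationTranscript, read_alignments, read_gtf,
                 read_star_junctions, write_gene_fasta, write_gtf,
                 write_isoform_fasta)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    genes: list[iso.GeneModel]
    peaks: dict[ep.TrackKey, list[ep.EndPeak]]
    rejects: list[tuple[str, str]]
    replicates: list[str]
    reads_by_replicate: dict[str, list[pp.AlignedRead]]
    stats: dict = field(default_factory=dict)

    @property
    def isoforms(self) -> list[iso.IsoformModel]:
        return [i for g in self.genes for i in g.isoforms]

    def tss_peaks(self) -> list[ep.EndPeak]:
        return [p for k, v in self.peaks.items() if k[2] == ep.FIVE_PRIME
                for p in v]

    def pa_peaks(self) -> list[ep.EndPeak]:
        return [p for k, v in self.peaks.items() if k[2] == ep.THREE_PRIME
                for p in v]


def prepare_reads(fastqs: Mapping[str, str | Path], genome: str | Path,
                  config: PipelineConfig, work_dir: str | Path,
                  threads: int = 1) -> dict[str, Path]:
    """Quality-filter, poly(A)-trim and align FASTQ replicates; returns SAM paths."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    sams: dict[str, Path] = {}
    for rep in sorted(fastqs):
        trimmed = work_dir / f"{rep}.trimmed.fastq"
        n = 0
        with open(trimmed, "w") as out:
            for rec in pp.filter_by_quality(pp.read_fastq(fastqs[rep]),
                                            config.quality_min):
                seq = pp.trim_polya(str(rec.seq), config.polya_adapter_len,
                                    config.polya_error_rate)
                if not seq:
                    continue
                quals = rec.letter_annotations["phred_quality"][:len(seq)]
                out.write(f"@{rec.id}\n{seq}\n+\n"
                          f"{''.join(chr(q + 33) for q in quals)}\n")
                n += 1
        log.info("%s: %d reads after quality filter and poly(A) trimming", rep, n)
        sam = work_dir / f"{rep}.sam"
        pp.align_reads([trimmed], genome, sam, config.aligner_args,
                       threads=threads)
        sams[rep] = sam
    return sams


def run_pipeline(alignments: Mapping[str, str | Path],
                 config: PipelineConfig | None = None,
                 annotation: Sequence[AnnotationTranscript] | str | Path | None = None,
                 splice_sites: Sequence[str | Path] | None = None,
                 make_downsampling: bool = False,
                 annotation_free_downsampling: bool | None = None,
                 extra_filter_iso: bool = False,
                 seed: int = 0,
                 genome=None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the reconstruction pipeline from per-replicate SAM/BAM files.

    Parameters
    ----------
    alignments
        Mapping replicate label -> SAM/BAM path (>= 2 replicates).
    annotation
        Optional annotation: a GTF path or parsed transcripts; used for
        annotation-mode downsampling, gene naming, and (absent explicit
        splice sites) as a junction reference.
    splice_sites
        Optional junction files (STAR SJ.out.tab or 4-column TSV); enables
        the splice-correction stage.
    make_downsampling
        Cap reads over highly expressed genes (annotation mode when an
        annotation is available, else annotation-free coverage capping).
    extra_filter_iso
        Apply the minor-isoform (1%-of-major) filter.
    genome
        Genome (path to FASTA, or mapping chrom -> sequence); required only
        for FASTA outputs.
    out_dir
        When given, write models.gtf, isoforms.fa, genes.fa,
        pseudo_alignments.txt, counts.tsv and rejects.tsv there.
    """
    config = config or PipelineConfig()
    replicates = sorted(alignments)
    config.check_replicates(len(replicates))

    if isinstance(annotation, (str, Path)):
        annotation = read_gtf(annotation)

    reads_by_rep: dict[str, list[pp.AlignedRead]] = {}
    for rep in replicates:
        records = read_alignments(alignments[rep], rep)
        reads_by_rep[rep] = pp.unique_alignment_filter(records)
        splice.fill_read_introns(reads_by_rep[rep])

    stats: dict = {"reads_in": {r: len(v) for r, v in reads_by_rep.items()}}

    junction_ref = None
    if splice_sites:
        table = read_star_junctions(list(splice_sites))
        junction_ref = splice.JunctionSet.from_table(
            table, min_samples=config.junction_min_samples)
    elif annotation is not None:
        junction_ref = splice.JunctionSet.from_annotation(annotation)
    if junction_ref is not None:
        for rep in replicates:
            stats.setdefault("splice_correction", {})[rep] = \
                splice.correct_read_introns(
                    reads_by_rep[rep], junction_ref, config.splice_tolerance_bp,
                    strand_aware=config.strand_aware_correction)

    if make_downsampling:
        use_annotation = (annotation is not None
                          and not annotation_free_downsampling)
        for rep in replicates:
            if use_annotation:
                reads_by_rep[rep] = ds.downsample_annotated(
                    reads_by_rep[rep], annotation, config.downsample_cap,
                    config.min_gene_reads, seed=seed, replicate=rep)
            else:
                reads_by_rep[rep] = ds.downsample_annotation_free(
                    reads_by_rep[rep], config.downsample_cap, seed=seed,
                    replicate=rep)
    stats["reads_used"] = {r: len(v) for r, v in reads_by_rep.items()}

    peaks = ep.call_all_peaks(
        reads_by_rep, config.support_min_replicates, config.pooled_cutoff,
        config.merge_dist_bp, strict=config.cutoff_strict)
    tss_index = ep.PeakIndex(peaks, ep.FIVE_PRIME)
    pa_index = ep.PeakIndex(peaks, ep.THREE_PRIME)

    all_reads = [r for rep in replicates for r in reads_by_rep[rep]]
    candidates, rejects = iso.group_reads(all_reads, tss_index, pa_index)
    retained = iso.filter_by_replicates(candidates, config.high_count,
                                        config.low_count)
    isoform_models = iso.build_isoforms(retained)
    genes = iso.cluster_genes(isoform_models, config.gene_overlap_frac)
    iso.assign_gene_ids(genes, annotation, config.gene_overlap_frac)
    if extra_filter_iso:
        genes = [iso.filter_minor_isoforms(g, config.minor_frac)
                 for g in genes]
    stats["n_isoforms"] = sum(len(g.isoforms) for g in genes)
    stats["n_genes"] = len(genes)
    log.info("reconstructed %d isoforms in %d genes",
             stats["n_isoforms"], stats["n_genes"])

    result = PipelineResult(genes, peaks, rejects, replicates, reads_by_rep,
                            stats)
    if out_dir is not None:
        write_outputs(result, out_dir, genome=genome)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  genome=None) -> dict[str, Path]:
    """Write the standard output set; FASTA outputs need the genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"gtf": out_dir / "models.gtf",
             "counts": out_dir / "counts.tsv",
             "rejects": out_dir / "rejects.tsv",
             "pseudo": out_dir / "pseudo_alignments.txt"}
    write_gtf(result.genes, paths["gtf"])
    iso.write_counts(result.genes, result.replicates, paths["counts"])
    iso.write_rejects(result.rejects, paths["rejects"])
    iso.write_pseudo_alignments(result.genes, paths["pseudo"])
    if genome is not None:
        if isinstance(genome, (str, Path)):
            from pyfaidx import Fasta
            genome = Fasta(str(genome))
        paths["isoform_fasta"] = out_dir / "isoforms.fa"
        paths["gene_fasta"] = out_dir / "genes.fa"
        write_isoform_fasta(result.genes, genome, paths["isoform_fasta"])
        write_gene_fasta(result.genes, genome, paths["gene_fasta"])
    return paths
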