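"""Pipeline configuration.

All tunable thresholds of the reconstruction pipeline live in one object so
that the CLI, a ``key=value`` config file, and library callers share a single
source of defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds and parameters of the isoform-reconstruction pipeline.

    Attributes
    ----------
    splice_tolerance_bp
        Maximum distance (bp) between each boundary of an alignment gap and
        the corresponding boundary of a reference intron for the gap to be
        corrected to that intron.
    downsample_cap
        Maximum number of reads retained per gene (annotation mode) or
        maximum per-base coverage (annotation-free mode) by the optional
        downsampling stage.
    min_gene_reads
        Genes with fewer attributed reads than this are ignored by the
        annotation-mode downsampler.
    support_min_replicates
        Number of replicates in which a position must have nonzero end
        coverage to enter the pooled track.
    pooled_cutoff
        Pooled-count cutoff for peak calling; positions with pooled count
        strictly greater than this are cluster candidates (set
        ``cutoff_strict=False`` for >=).
    merge_dist_bp
        Two candidate positions join one cluster when the number of
        intervening non-candidate positions is smaller than this.
    high_count
        An isoform needs at least this many reads in one replicate.
    low_count
        ... and at least this many reads in a second, different replicate.
    gene_overlap_frac
        Fraction of the shorter span that must be shared for two isoforms
        (or a gene and an annotated gene) to be joined/named.
    minor_frac
        A non-major isoform of a gene is kept only if its read count exceeds
        this fraction of the major isoform's count.
    quality_min
        Minimum whole-read mean Phred quality (mean taken in probability
        space) for a read to pass quality filtering.
    polya_adapter_len
        Length of the poly(A) adapter model used for 3' tail trimming.
    polya_error_rate
        Maximum per-length mismatch rate of an admissible poly(A) match.
    junction_min_samples
        A reference splice junction must be seen in at least this many
        distinct samples.
    aligner_args
        Arguments passed verbatim to the external splice-aware aligner.
    cutoff_strict
        Whether the pooled cutoff is a strict inequality (default) or >=.
    strand_aware_correction
        If True, splice correction only considers reference introns on the
        read's strand; by default matching is purely coordinate-based and
        strand-undefined junctions match reads of either strand.
    """

    splice_tolerance_bp: int = 10
    downsample_cap: int = 1000
    min_gene_reads: int = 5
    support_min_replicates: int = 2
    pooled_cutoff: int = 2
    merge_dist_bp: int = 10
    high_count: int = 5
    low_count: int = 1
    gene_overlap_frac: float = 0.8
    minor_frac: float = 0.01
    quality_min: float = 7.0
    polya_adapter_len: int = 100
    polya_error_rate: float = 0.1
    junction_min_samples: int = 2
    aligner_args: str = "-ax splice -k14 -uf -G 10k"
    cutoff_strict: bool = True
    strand_aware_correction: bool = False

    _INT_FIELDS = {
        "splice_tolerance_bp", "downsample_cap", "min_gene_reads",
        "support_min_replicates", "pooled_cutoff", "merge_dist_bp",
        "high_count", "low_count", "polya_adapter_len", "junction_min_samples",
    }
    _FLOAT_FIELDS = {"gene_overlap_frac", "minor_frac", "quality_min",
                     "polya_error_rate"}
    _BOOL_FIELDS = {"cutoff_strict", "strand_aware_correction"}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._INT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gene_overlap_frac", "minor_frac", "polya_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def check_replicates(self, n_replicates: int) -> None:
        if n_replicates < self.support_min_replicates:
            raise ValueError(
                f"support_min_replicates={self.support_min_replicates} exceeds "
                f"the number of supplied replicates ({n_replicates})"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Build a config from a ``key=value`` file; keyword overrides win."""
        values: dict = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in names:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            if key in cls._INT_FIELDS:
                values[key] = int(val)
            elif key in cls._FLOAT_FIELDS:
                values[key] = float(val)
            elif key in cls._BOOL_FIELDS:
                values[key] = val.lower() in ("1", "true", "yes", "on")
            else:
                values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
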