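"""Shared domain types for transcriptome-map analysis.

Coordinates are 1-based inclusive internally (GFF3 convention); interval
files exported to disk use BED 0-based half-open coordinates. Strand is
carried through but never consulted by any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np

#: Tissue panel of the bovine brain/pituitary study this pipeline was
#: designed around: anterior pituitary, amygdala, hippocampus, dorsal and
#: ventral hypothalamus.
DEFAULT_TISSUES = ("AP", "AM", "HC", "DH", "VH")

RIDGE = "RIDGE"
ANTIRIDGE = "ANTIRIDGE"
INTERMEDIATE = "INTERMEDIATE"


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``transcripts`` is a tuple of transcripts, each an ordered tuple of
    exon ``(start, end)`` intervals, 1-based inclusive, sorted and
    non-overlapping within a transcript.  ``gc_fraction`` is the gene's GC
    content in [0, 1], taken from the annotation (not computed from
    sequence).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    transcripts: tuple[tuple[tuple[int, int], ...], ...] = ()
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        for t in self.transcripts:
            if not t:
                raise ValueError(f"gene {self.gene_id}: empty transcript")
            prev_end = None
            for s, e in t:
                if e < s:
                    raise ValueError(f"gene {self.gene_id}: exon end < start")
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"gene {self.gene_id}: exon [{s},{e}] outside gene body"
                    )
                if prev_end is not None and s <= prev_end:
                    raise ValueError(
                        f"gene {self.gene_id}: exons unsorted or overlapping"
                    )
                prev_end = e

    @property
    def length(self) -> int:
        """Genomic length in bp (1-based inclusive span)."""
        return self.end - self.start + 1


class GeneOrderIndex:
    """Genes ordered along each chromosome.

    The order is the unit in which window sizes and stretch lengths are
    counted ("gene positions").  Sorting is by (start, end, gene_id) so the
    order is strict and deterministic even for coincident coordinates.
    """

    def __init__(
        self,
        genes: Mapping[str, GeneModel],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        self.order: dict[str, list[str]] = {}
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom in sorted(by_chrom):
            gs = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            self.order[chrom] = [g.gene_id for g in gs]
            self.starts[chrom] = np.array([g.start for g in gs], dtype=np.int64)
            self.ends[chrom] = np.array([g.end for g in gs], dtype=np.int64)
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(self.ends[c].max()) for c in self.order if len(self.ends[c])
            }
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.order)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def n_genes(self) -> int:
        return sum(len(v) for v in self.order.values())


@dataclass
class Annotation:
    """A gene annotation: GeneModels keyed by id plus their order index."""

    genes: dict[str, GeneModel]
    index: GeneOrderIndex

    @classmethod
    def from_genes(
        cls,
        genes: Iterable[GeneModel],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "Annotation":
        d: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in d:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            d[g.gene_id] = g
        return cls(genes=d, index=GeneOrderIndex(d, chrom_lengths))

    def __len__(self) -> int:
        return len(self.genes)


class ExpressionMatrix:
    """Normalized log2-intensity expression values, one row per gene.

    ``values`` is a pandas DataFrame (genes x tissues).  ``negative_controls``
    is a flat array of control-probe log intensities used to derive the
    expressed/not-expressed threshold.  ``unmapped_genes`` records genes
    present in the matrix but absent from the annotation it was loaded
    against (they stay in the matrix, flagged).
    """

    def __init__(self, values, negative_controls=None, unmapped_genes=None):
        import pandas as pd

        values = pd.DataFrame(values)
        if values.shape[1] == 0:
            raise ValueError("expression matrix needs at least one tissue")
        if not values.index.is_unique:
            raise ValueError("expression matrix has duplicate gene rows")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        self.values = values
        self.negative_controls = (
            np.asarray([], dtype=float)
            if negative_controls is None
            else np.asarray(negative_controls, dtype=float)
        )
        self.unmapped_genes: set[str] = set(unmapped_genes or ())

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def tissue_values(self, tissue: str) -> "np.ndarray":
        """Per-gene values for one tissue, or the across-tissue mean for
        ``"average"``."""
        if tissue == "average":
            return self.values.to_numpy(dtype=float).mean(axis=1)
        if tissue not in self.values.columns:
            raise KeyError(f"unknown tissue {tissue!r}")
        return self.values[tissue].to_numpy(dtype=float)

    def gene_value_map(self, tissue: str) -> dict[str, float]:
        vals = self.tissue_values(tissue)
        return dict(zip(self.values.index, vals))


@dataclass
class RegionCall:
    """A called RIDGE or anti-RIDGE.

    ``start``/``end`` are 1-based inclusive bp.  ``n_gene_positions`` counts
    the map positions in the qualifying stretch; ``member_genes`` lists every
    annotation gene overlapping the interval by at least 1 bp.
    """

    chrom: str
    start: int
    end: int
    kind: str
    n_gene_positions: int
    member_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (RIDGE, ANTIRIDGE):
            raise ValueError(f"bad region kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("region end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    Defaults are the study's operating point: a 39-gene moving-median
    window, stretches of at least 10 qualifying gene positions, fold
    thresholds 1.25 (up) / 1.45 (down) re-calibrated to ~10% genome
    coverage per region kind, a 99.9% negative-control quantile expression
    threshold, and 10,000 Monte-Carlo replicates for both the permutation
    and the resampling null.
    """

    window: int = 39
    min_stretch: int = 10
    coverage_target: float = 0.10
    fold_up: float = 1.25
    fold_down: float = 1.45
    control_quantile: float = 0.999
    n_perm: int = 10_000
    n_samp: int = 10_000
    grid_step: float = 0.05
    fold_max: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.min_stretch < 1:
            raise ValueError("min_stretch must be >= 1")
        if not 0 < self.coverage_target < 1:
            raise ValueError("coverage_target must be in (0, 1)")
        if self.fold_up <= 1 or self.fold_down <= 1:
            raise ValueError("fold thresholds must exceed 1")
        if not 0 < self.control_quantile < 1:
            raise ValueError("control_quantile must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class ChromosomeMap:
    """Gene-ordered expression profile of one chromosome."""

    gene_ids: list[str]
    positions: np.ndarray  # gene start anchors, bp
    gene_ends: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray


@dataclass
class TranscriptomeMap:
    """Per-chromosome running-median transcriptome maps for one tissue
    (or the tissue average)."""

    chroms: dict[str, ChromosomeMap]
    window: int
    tissue: str
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def concatenated_smoothed(self) -> np.ndarray:
        """Genome-wide concatenation (chromosome name order) of smoothed
        values; the unit compared between tissues."""
        parts = [self.chroms[c].smoothed for c in sorted(self.chroms)]
        return np.concatenate(parts) if parts else np.asarray([], dtype=float)

    def all_raw(self) -> np.ndarray:
        parts = [self.chroms[c].raw for c in sorted(self.chroms)]
        return np.concatenate(parts) if parts else np.asarray([], dtype=float)

    def n_positions(self) -> int:
        return sum(len(m.gene_ids) for m in self.chroms.values())


@dataclass
class NullDistribution:
    """A Monte-Carlo null: per-replicate statistic values plus summaries.

    ``p_empirical`` uses the add-one correction (#{null >= obs}+1)/(B+1);
    ``p_plain`` is the uncorrected proportion.
    """

    n: int
    values: np.ndarray
    observed: float
    direction: str = "ge"  # tail used: "ge" (enrichment) or "le" (depletion)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0

    def _tail_count(self) -> int:
        if self.direction == "ge":
            return int(np.sum(self.values >= self.observed))
        return int(np.sum(self.values <= self.observed))

    @property
    def p_empirical(self) -> float:
        return (self._tail_count() + 1) / (self.n + 1)

    @property
    def p_plain(self) -> float:
        return self._tail_count() / self.n

    def summary(self) -> dict:
        return {
            "n": self.n,
            "observed": self.observed,
            "mean": self.mean,
            "sd": self.sd,
            "direction": self.direction,
            "p_empirical": self.p_empirical,
            "p_plain": self.p_plain,
        }


@dataclass
class CalibrationResult:
    """Outcome of tuning a fold threshold to a genome-coverage target."""

    direction: str  # "up" or "down"
    fold: float
    coverage: float
    grid_step: float
    curve: dict[float, float] = field(default_factory=dict)
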