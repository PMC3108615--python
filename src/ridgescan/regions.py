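"""RIDGE / anti-RIDGE calling, coverage calibration and the permutation null.

A gene position qualifies when its smoothed (running-median) value is
strictly above ``m * fold`` (up) or strictly below ``m / fold`` (down),
where ``m`` is the genomic median of the raw per-gene values.  Maximal runs
of at least ``min_stretch`` qualifying positions become regions; a region's
genomic extent spans from the first qualifying gene's start to the last
qualifying gene's end.  Fold thresholds are calibrated so that regions of
each kind cover a target fraction (default 10%) of the genome.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .maps import build_map, running_median
from .model import (
    ANTIRIDGE,
    Annotation,
    CalibrationResult,
    ExpressionMatrix,
    NullDistribution,
    PipelineConfig,
    RegionCall,
    RIDGE,
    TranscriptomeMap,
)

logger = logging.getLogger("ridgescan")


def genomic_median(tmap: TranscriptomeMap) -> float:
    """Median of the raw (unsmoothed) per-gene values over all map genes."""
    raw = tmap.all_raw()
    if raw.size == 0:
        raise ValueError("empty transcriptome map")
    return float(np.median(raw))


def _qualifying(smoothed: np.ndarray, m: float, fold: float, direction: str):
    if direction == "up":
        return smoothed > m * fold
    if direction == "down":
        return smoothed < m / fold
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def _runs(mask: np.ndarray, k: int):
    """Maximal runs of True of length >= k as (start, stop) index pairs."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    for s, e in zip(starts, stops):
        if e - s >= k:
            yield int(s), int(e)


def call_regions(
    tmap: TranscriptomeMap,
    m: float,
    fold: float,
    direction: str,
    min_stretch: int = 10,
    annotation: Annotation | None = None,
) -> list[RegionCall]:
    """Call regions of one kind on every chromosome of a map.

    ``member_genes`` holds every annotation gene overlapping the region
    interval by >= 1 bp (any-overlap rule); when no annotation is supplied
    it falls back to the map genes of the qualifying run.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if min_stretch < 1:
        raise ValueError("min_stretch must be >= 1")
    kind = RIDGE if direction == "up" else ANTIRIDGE
    regions: list[RegionCall] = []
    for chrom in sorted(tmap.chroms):
        cm = tmap.chroms[chrom]
        mask = _qualifying(cm.smoothed, m, fold, direction)
        for s, e in _runs(mask, min_stretch):
            start = int(cm.positions[s:e].min())
            end = int(cm.gene_ends[s:e].max())
            if annotation is not None:
                members = _overlapping_genes(annotation, chrom, start, end)
            else:
                members = tuple(cm.gene_ids[s:e])
            regions.append(
                RegionCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    kind=kind,
                    n_gene_positions=e - s,
                    member_genes=members,
                )
            )
    return regions


def _overlapping_genes(annotation: Annotation, chrom: str, start: int, end: int):
    idx = annotation.index
    if chrom not in idx.order:
        return ()
    starts, ends = idx.starts[chrom], idx.ends[chrom]
    hit = (starts <= end) & (ends >= start)
    return tuple(np.asarray(idx.order[chrom], dtype=object)[hit])


def count_regions(smoothed_by_chrom, m: float, fold: float, direction: str,
                  min_stretch: int) -> int:
    """Region count only — the statistic recorded by the permutation null."""
    total = 0
    for smoothed in smoothed_by_chrom:
        mask = _qualifying(smoothed, m, fold, direction)
        total += sum(1 for _ in _runs(mask, min_stretch))
    return total


def coverage(
    regions: Sequence[RegionCall],
    chrom_lengths: dict[str, int],
    unit: str = "bp",
    n_genes: int | None = None,
) -> float:
    """Fraction of the genome (bp, default) covered by the regions.

    ``unit="genes"`` instead reports the fraction of gene positions inside
    regions (``n_genes`` = total map gene count), for sensitivity analysis.
    """
    if unit == "genes":
        if not n_genes:
            raise ValueError("unit='genes' needs the total gene count")
        return sum(r.n_gene_positions for r in regions) / n_genes
    genome = sum(chrom_lengths.values())
    if genome <= 0:
        raise ValueError("genome length is zero")
    return sum(r.length for r in regions) / genome


def calibrate(
    tmap: TranscriptomeMap,
    direction: str,
    target: float = 0.10,
    grid_step: float = 0.05,
    fold_max: float = 3.0,
    min_stretch: int = 10,
    m: float | None = None,
) -> CalibrationResult:
    """Scan fold thresholds on a grid and pick the one whose called regions
    cover the genome closest to ``target``; ties go to the larger (more
    stringent) fold.  If every grid fold yields zero coverage the smallest
    grid fold is returned with a warning."""
    if not 0 < target < 1:
        raise ValueError("coverage target must be in (0, 1)")
    if m is None:
        m = genomic_median(tmap)
    grid = []
    f = 1.0 + grid_step
    while f <= fold_max + 1e-9:
        grid.append(round(f, 10))
        f += grid_step
    curve: dict[float, float] = {}
    for f in grid:
        regs = call_regions(tmap, m, f, direction, min_stretch)
        curve[f] = coverage(regs, tmap.chrom_lengths)
    if all(c == 0.0 for c in curve.values()):
        logger.warning("calibration (%s): zero coverage over the whole grid", direction)
        f_best = grid[0]
    else:
        # tie -> larger fold: iterate ascending, accept when strictly better
        # or equally good.
        f_best = grid[0]
        for f in grid:
            if abs(curve[f] - target) <= abs(curve[f_best] - target):
                f_best = f
    return CalibrationResult(
        direction=direction,
        fold=f_best,
        coverage=curve[f_best],
        grid_step=grid_step,
        curve=curve,
    )


def permutation_test(
    expr: ExpressionMatrix,
    annotation: Annotation,
    config: PipelineConfig,
    direction: str,
    seed: int | np.random.Generator | None = None,
    tissue: str = "average",
    n_perm: int | None = None,
    fold: float | None = None,
) -> NullDistribution:
    """Null distribution of the region count under random gene placement.

    Gene positions stay fixed; the assignment of expression values to
    positions is shuffled genome-wide, the maps are rebuilt and regions
    re-called with the same window, fold and stretch settings as the
    observed call.  The genomic median is permutation-invariant (same value
    multiset) and is computed once.
    """
    n_perm = config.n_perm if n_perm is None else n_perm
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if fold is None:
        fold = config.fold_up if direction == "up" else config.fold_down
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.rng_seed if seed is None else seed)
    )
    tmap = build_map(expr, annotation, tissue=tissue, window=config.window)
    m = genomic_median(tmap)
    chrom_order = sorted(tmap.chroms)
    raw_concat = np.concatenate([tmap.chroms[c].raw for c in chrom_order])
    sizes = [len(tmap.chroms[c].raw) for c in chrom_order]
    bounds = np.cumsum([0] + sizes)
    observed = count_regions(
        [tmap.chroms[c].smoothed for c in chrom_order],
        m, fold, direction, config.min_stretch,
    )
    counts = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(raw_concat)
        smoothed = [
            running_median(perm[bounds[i]:bounds[i + 1]], config.window)
            for i in range(len(sizes))
        ]
        counts[b] = count_regions(smoothed, m, fold, direction, config.min_stretch)
    return NullDistribution(
        n=n_perm, values=counts, observed=float(observed), direction="ge"
    )


def regions_interval_trees(regions: Sequence[RegionCall]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over region calls (half-open, bp)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r.kind)
    return trees
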