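"""Running-median transcriptome maps.

A transcriptome map orders the genes of a chromosome by position and
replaces each gene's expression value by the median over a window of ``w``
gene positions centred on it (w = 39 by default: the gene and 19 flanking
genes on either side).  Near chromosome ends the window half-width shrinks
symmetrically, so the first and last values equal the raw values and the
interior definition is recovered as soon as a full window fits.  This end
rule matches R's ``runmed(..., endrule="med")``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .model import Annotation, ChromosomeMap, ExpressionMatrix, TranscriptomeMap


def running_median(values, w: int) -> np.ndarray:
    """Moving median with symmetrically shrinking end windows.

    Position ``i`` (0-based) gets the median of
    ``values[i-h : i+h+1]`` with ``h = min(i, n-1-i, (w-1)//2)``.
    Output length equals input length; ``w`` must be odd.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {w}")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return values.copy()
    h = (w - 1) // 2
    out = np.empty(n, dtype=float)
    if n >= w:
        out[h : n - h] = np.median(sliding_window_view(values, w), axis=1)
    for i in range(min(h, n)):
        hi = min(i, n - 1 - i, h)
        out[i] = np.median(values[i - hi : i + hi + 1])
        j = n - 1 - i
        hj = min(j, n - 1 - j, h)
        out[j] = np.median(values[j - hj : j + hj + 1])
    return out


def build_map(
    expr: ExpressionMatrix,
    annotation: Annotation,
    tissue: str = "average",
    window: int = 39,
) -> TranscriptomeMap:
    """Build per-chromosome running-median maps for one tissue.

    ``tissue="average"`` uses the arithmetic mean of the per-tissue values
    for each gene.  Genes without an expression value are left out of the
    map (they remain annotation genes); chromosomes keep their annotation
    gene order.
    """
    gene_values = expr.gene_value_map(tissue)
    idx = annotation.index
    chroms: dict[str, ChromosomeMap] = {}
    for chrom in idx.chromosomes:
        ids, positions, ends, raw = [], [], [], []
        for gid, s, e in zip(idx.order[chrom], idx.starts[chrom], idx.ends[chrom]):
            v = gene_values.get(gid)
            if v is None:
                continue
            ids.append(gid)
            positions.append(int(s))
            ends.append(int(e))
            raw.append(v)
        if not ids:
            continue
        raw_arr = np.asarray(raw, dtype=float)
        chroms[chrom] = ChromosomeMap(
            gene_ids=ids,
            positions=np.asarray(positions, dtype=np.int64),
            gene_ends=np.asarray(ends, dtype=np.int64),
            raw=raw_arr,
            smoothed=running_median(raw_arr, window),
        )
    return TranscriptomeMap(
        chroms=chroms,
        window=window,
        tissue=tissue,
        chrom_lengths=dict(idx.chrom_lengths),
    )


def map_correlation(map_a: TranscriptomeMap, map_b: TranscriptomeMap):
    """Spearman rank correlation between two transcriptome maps.

    Compares the genome-wide concatenation of smoothed values (same gene
    order required).  Ties get midranks; the p-value is the large-sample
    t approximation.  Returns ``(rho, p)``.
    """
    a = map_a.concatenated_smoothed()
    b = map_b.concatenated_smoothed()
    if a.size != b.size:
        raise ValueError("maps cover different gene sets")
    if a.size < 3:
        raise ValueError("need at least 3 paired map positions")
    for ca, cb in zip(sorted(map_a.chroms), sorted(map_b.chroms)):
        if map_a.chroms[ca].gene_ids != map_b.chroms[cb].gene_ids:
            raise ValueError("maps are not in the same gene order")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def write_map_tsv(tmap: TranscriptomeMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tgene_id\tposition\traw\tsmoothed\n")
        for chrom in sorted(tmap.chroms):
            m = tmap.chroms[chrom]
            for gid, pos, r, s in zip(m.gene_ids, m.positions, m.raw, m.smoothed):
                fh.write(f"{chrom}\t{gid}\t{pos}\t{r:.12g}\t{s:.12g}\n")
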