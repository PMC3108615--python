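import numpy as np
import pandas as pd
import pytest

from ridgescan import (
    Annotation,
    ExpressionMatrix,
    GeneModel,
    generate_expression,
    generate_genome,
)
from ridgescan.model import ChromosomeMap, TranscriptomeMap


@pytest.fixture(scope="session")
def small_simulation():
    """One 2000-gene chromosome with planted domains (default conditions)."""
    annotation, truth = generate_genome(n_chrom=1, genes_per_chrom=2000, seed=11)
    expr = generate_expression(annotation, truth, seed=12)
    return annotation, truth, expr


@pytest.fixture
def toy_annotation():
    """Five equal genes on one chromosome, plus one on a second."""
    genes = [
        GeneModel(f"g{i}", "chr1", 1000 * i + 1, 1000 * i + 800, "+")
        for i in range(5)
    ]
    genes.append(GeneModel("gX", "chr2", 51, 900, "-"))
    return Annotation.from_genes(genes, {"chr1": 6000, "chr2": 1000})


@pytest.fixture
def toy_expression(toy_annotation):
    genes = list(toy_annotation.genes)
    values = pd.DataFrame(
        np.tile(np.array([10.0, 11.0, 12.0, 9.0, 10.5, 10.0]), (5, 1)).T,
        index=genes,
        columns=["AP", "AM", "HC", "DH", "VH"],
    )
    return ExpressionMatrix(values, negative_controls=np.full(100, 9.0))


def make_map(smoothed_blocks, gene_span=1000, chrom="chr1", chrom_length=None,
             raw=None, window=1):
    """Build a TranscriptomeMap with prescribed smoothed values.

    ``smoothed_blocks`` is a flat list of smoothed values; genes are laid
    out back to back, each ``gene_span`` bp long.
    """
    smoothed = np.asarray(smoothed_blocks, dtype=float)
    n = smoothed.size
    starts = np.arange(n, dtype=np.int64) * gene_span + 1
    ends = starts + gene_span - 1
    cm = ChromosomeMap(
        gene_ids=[f"m{i}" for i in range(n)],
        positions=starts,
        gene_ends=ends,
        raw=smoothed.copy() if raw is None else np.asarray(raw, float),
        smoothed=smoothed,
    )
    length = chrom_length if chrom_length is not None else int(ends[-1])
    return TranscriptomeMap(
        chroms={chrom: cm}, window=window, tissue="average",
        chrom_lengths={chrom: length},
    )
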