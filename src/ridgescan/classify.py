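"""Housekeeping / tissue-specific gene classification and gene-set tests.

"Expressed" means strictly above a threshold derived from the
negative-control intensity distribution (its 99.9% quantile by default).
A gene expressed in every tissue of the panel is housekeeping (HK); in
exactly one tissue, tissue-specific (TS); in none, silent; otherwise
intermediate.  The labels are explicitly relative to the supplied panel.

Two set-level tests accompany the classification: a without-replacement
resampling test for over/under-representation of a gene set among region
genes, and Fisher's exact test on the distribution of a query gene list
across RIDGE / anti-RIDGE / intermediate territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import (
    ANTIRIDGE,
    ExpressionMatrix,
    INTERMEDIATE,
    NullDistribution,
    RegionCall,
    RIDGE,
)

logger = logging.getLogger("ridgescan")

HK = "HK"
TS = "TS"
SILENT = "silent"
INTERMEDIATE_CLASS = "intermediate"


def expression_threshold(controls, q: float = 0.999) -> float:
    """Expression threshold: the ``q`` quantile of the negative-control
    intensities, by linear interpolation of order statistics
    (``numpy.quantile`` default)."""
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("no negative-control intensities")
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(controls, q))


@dataclass
class ExpressionClassification:
    """Per-gene expressed-tissue sets and HK/TS/intermediate/silent labels."""

    table: pd.DataFrame  # bool column per tissue + n_expressed + label
    threshold: float
    tissues: tuple[str, ...]

    def genes_with_label(self, label: str) -> set[str]:
        if label == TS:
            mask = self.table["label"].str.startswith("TS")
        else:
            mask = self.table["label"] == label
        return set(self.table.index[mask])

    def class_counts(self) -> dict[str, int]:
        counts = {HK: 0, TS: 0, INTERMEDIATE_CLASS: 0, SILENT: 0}
        for lab in self.table["label"]:
            counts[TS if lab.startswith("TS") else lab] += 1
        return counts


def classify_genes(expr: ExpressionMatrix, threshold: float) -> ExpressionClassification:
    """Classify every gene by the number of tissues in which it is
    expressed (value strictly above ``threshold``)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    tissues = tuple(expr.tissues)
    expressed = expr.values.to_numpy(dtype=float) > threshold
    n_expressed = expressed.sum(axis=1)
    labels = []
    for row, n in zip(expressed, n_expressed):
        if n == len(tissues):
            labels.append(HK)
        elif n == 1:
            labels.append(f"TS:{tissues[int(np.flatnonzero(row)[0])]}")
        elif n == 0:
            labels.append(SILENT)
        else:
            labels.append(INTERMEDIATE_CLASS)
    table = pd.DataFrame(expressed, index=expr.values.index, columns=list(tissues))
    table["n_expressed"] = n_expressed
    table["label"] = labels
    return ExpressionClassification(table=table, threshold=threshold, tissues=tissues)


@dataclass
class OverlapTestResult:
    """Resampling test of a gene set's overlap with region genes."""

    observed_percent: float
    null: NullDistribution
    direction: str  # "enrichment" or "depletion"
    n_query: int
    n_universe: int

    @property
    def p_empirical(self) -> float:
        return self.null.p_empirical

    def summary(self) -> dict:
        return {
            "observed_percent": self.observed_percent,
            "direction": self.direction,
            "n_query": self.n_query,
            "n_universe": self.n_universe,
            **{f"null_{k}": v for k, v in self.null.summary().items()},
        }


def overlap_resampling_test(
    query: Iterable[str],
    region_genes: Iterable[str],
    universe: Sequence[str],
    n_samp: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> OverlapTestResult:
    """Monte-Carlo over/under-representation test.

    Each replicate draws ``|query|`` genes from the universe *without
    replacement* and records the percentage falling in ``region_genes``;
    the null is therefore hypergeometric.  The reported tail follows the
    observed direction of deviation from the null mean, with the add-one
    empirical p-value.
    """
    universe = list(universe)
    query = set(query)
    region_genes = set(region_genes)
    n = len(query)
    N = len(universe)
    if n == 0:
        raise ValueError("empty query set")
    if n > N:
        raise ValueError(f"query size {n} exceeds universe size {N}")
    extra = query - set(universe)
    if extra:
        raise ValueError(f"{len(extra)} query genes not in universe")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = 100.0 * len(query & region_genes) / n
    member = np.fromiter(
        (g in region_genes for g in universe), dtype=bool, count=N
    )
    percents = np.empty(n_samp, dtype=float)
    for b in range(n_samp):
        idx = rng.choice(N, size=n, replace=False)
        percents[b] = 100.0 * member[idx].sum() / n
    expected = 100.0 * member.sum() / N
    direction = "enrichment" if observed >= expected else "depletion"
    null = NullDistribution(
        n=n_samp,
        values=percents,
        observed=observed,
        direction="ge" if direction == "enrichment" else "le",
    )
    return OverlapTestResult(
        observed_percent=observed,
        null=null,
        direction=direction,
        n_query=n,
        n_universe=N,
    )


def hypergeometric_overlap_sd(n: int, N: int, p: float) -> float:
    """Closed-form s.d. (percentage points) of the percent overlap when
    drawing ``n`` of ``N`` items without replacement, a fraction ``p`` of
    which are marked: ``100 * sqrt(p(1-p)/n * (N-n)/(N-1))``."""
    return 100.0 * float(np.sqrt(p * (1 - p) / n * (N - n) / (N - 1)))


# ---------------------------------------------------------------------------
# region category assignment + Fisher's exact test

def assign_region_category(
    gene_start: int,
    gene_end: int,
    chrom: str,
    regions: Sequence[RegionCall],
    warn_no_map: bool = True,
) -> str:
    """RIDGE / ANTIRIDGE if the gene overlaps a region of that kind by
    >= 1 bp, else INTERMEDIATE."""
    chroms_with_regions = {r.chrom for r in regions}
    for r in regions:
        if r.chrom == chrom and r.start <= gene_end and r.end >= gene_start:
            return r.kind
    if warn_no_map and chrom not in chroms_with_regions:
        logger.debug("gene on chromosome %s with no called regions", chrom)
    return INTERMEDIATE


def categorize_genes(
    annotation, gene_ids: Iterable[str], regions: Sequence[RegionCall]
) -> dict[str, str]:
    """Region category per gene, using per-chromosome interval trees."""
    from .regions import regions_interval_trees

    trees = regions_interval_trees(regions)
    out: dict[str, str] = {}
    for gid in gene_ids:
        g = annotation.genes.get(gid)
        if g is None:
            continue
        tree = trees.get(g.chrom)
        if tree is None:
            out[gid] = INTERMEDIATE
            continue
        hits = tree.overlap(g.start, g.end + 1)
        if hits:
            # a gene spanning two regions: the earliest-starting one wins
            out[gid] = min(hits, key=lambda iv: (iv.begin, iv.data)).data
        else:
            out[gid] = INTERMEDIATE
    return out


CATEGORIES = (RIDGE, ANTIRIDGE, INTERMEDIATE)


@dataclass
class RegionDistributionTest:
    """Fisher's exact test of query genes across region categories."""

    query_counts: dict[str, int]
    background_counts: dict[str, int]
    p_value: float  # 2x3 exact test
    p_value_2x2: float  # collapsed: anti-RIDGE vs rest
    table: list[list[int]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "query_counts": self.query_counts,
            "background_counts": self.background_counts,
            "p_value_2x3": self.p_value,
            "p_value_2x2_antiridge_vs_rest": self.p_value_2x2,
        }


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test for a 2 x C contingency table.

    Conditions on all margins and sums the probabilities of every table
    whose conditional probability does not exceed that of the observed
    table (the r x c generalisation used by R's ``fisher.test``).
    Enumeration runs over the free cells of the smaller row.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    col_sums = table.sum(axis=0)
    row_sums = table.sum(axis=1)
    if row_sums.min() == 0 or (col_sums == 0).all():
        logger.warning("degenerate margins in Fisher test; p = 1")
        return 1.0
    # drop empty columns: they contribute nothing
    keep = col_sums > 0
    table = table[:, keep]
    col_sums = col_sums[keep]
    r1 = int(table[0].sum())
    N = int(table.sum())

    def log_prob(x: tuple[int, ...]) -> float:
        # P(x) = prod_j C(c_j, x_j) / C(N, r1)
        lp = -(gammaln(N + 1) - gammaln(r1 + 1) - gammaln(N - r1 + 1))
        for cj, xj in zip(col_sums, x):
            lp += gammaln(cj + 1) - gammaln(xj + 1) - gammaln(cj - xj + 1)
        return float(lp)

    obs_lp = log_prob(tuple(int(v) for v in table[0]))
    C = len(col_sums)
    total = 0.0
    eps = 1e-7

    def recurse(j: int, remaining: int, x: list[int]):
        nonlocal total
        if j == C - 1:
            if remaining <= col_sums[j]:
                lp = log_prob(tuple(x + [remaining]))
                if lp <= obs_lp + eps:
                    total += np.exp(lp)
            return
        max_x = min(int(col_sums[j]), remaining)
        min_x = max(0, remaining - int(col_sums[j + 1:].sum()))
        for xj in range(min_x, max_x + 1):
            recurse(j + 1, remaining - xj, x + [xj])

    recurse(0, r1, [])
    return min(1.0, float(total))


def fisher_region_distribution(
    query_categories: Mapping[str, str] | Sequence[str],
    background_categories: Mapping[str, str] | Sequence[str],
) -> RegionDistributionTest:
    """Test whether query genes distribute across RIDGE / anti-RIDGE /
    intermediate differently from the background universe.

    ``background_categories`` is the category of every universe gene
    (including the query genes; the query row is subtracted to form the
    2 x 3 table).  Also reports the 2 x 2 collapse anti-RIDGE vs rest.
    """
    qvals = list(
        query_categories.values()
        if isinstance(query_categories, Mapping)
        else query_categories
    )
    bvals = list(
        background_categories.values()
        if isinstance(background_categories, Mapping)
        else background_categories
    )
    qc = {c: qvals.count(c) for c in CATEGORIES}
    bc = {c: bvals.count(c) for c in CATEGORIES}
    rest = [bc[c] - qc[c] for c in CATEGORIES]
    if min(rest) < 0:
        raise ValueError("query counts exceed background counts")
    table = np.array([[qc[c] for c in CATEGORIES], rest], dtype=np.int64)
    p3 = fisher_exact_2xc(table)
    collapsed = np.array(
        [
            [qc[ANTIRIDGE], qc[RIDGE] + qc[INTERMEDIATE]],
            [rest[1], rest[0] + rest[2]],
        ]
    )
    if collapsed.sum(axis=1).min() == 0 or collapsed.sum(axis=0).min() == 0:
        p2 = 1.0
    else:
        p2 = float(stats.fisher_exact(collapsed, alternative="two-sided")[1])
    return RegionDistributionTest(
        query_counts=qc,
        background_counts=bc,
        p_value=p3,
        p_value_2x2=p2,
        table=table.tolist(),
    )
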