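"""Per-gene genomic features and group comparisons.

Six features per gene: genomic gene length; mean intron length (pooled
over the introns of all transcripts; absent for intron-less genes); GC
fraction; mean transcript length (summed exon length per transcript);
mean exon count per transcript; mean exon length (pooled over all exons
of all transcripts).  Group contrasts (HK vs TS, RIDGE vs anti-RIDGE
members) use the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .model import Annotation

logger = logging.getLogger("ridgescan")

FEATURES = (
    "gene_length",
    "intron_length",
    "gc_fraction",
    "transcript_length",
    "exon_count",
    "exon_length",
)


def extract_features(
    annotation: Annotation, intron_mode: str = "pooled"
) -> pd.DataFrame:
    """FeatureTable: one row per gene, one column per feature.

    Introns are the gaps between consecutive exons within a transcript.
    ``intron_mode="pooled"`` averages over the pooled introns of all
    transcripts; ``"per_transcript"`` averages the per-transcript mean
    intron lengths.  Genes whose transcripts have overlapping exons are
    skipped with a warning (GeneModel construction normally forbids them).
    """
    if intron_mode not in ("pooled", "per_transcript"):
        raise ValueError("intron_mode must be 'pooled' or 'per_transcript'")
    rows = {}
    for gid, g in annotation.genes.items():
        rec = {
            "gene_length": float(g.length),
            "gc_fraction": np.nan if g.gc_fraction is None else float(g.gc_fraction),
            "intron_length": np.nan,
            "transcript_length": np.nan,
            "exon_count": np.nan,
            "exon_length": np.nan,
        }
        if g.transcripts:
            ok = True
            t_lengths, e_counts, exon_lens = [], [], []
            pooled_introns, per_t_means = [], []
            for t in g.transcripts:
                for (s1, e1), (s2, e2) in zip(t, t[1:]):
                    if s2 <= e1:
                        logger.warning("skipping %s: overlapping exons", gid)
                        ok = False
                        break
                if not ok:
                    break
                lens = [e - s + 1 for s, e in t]
                t_lengths.append(sum(lens))
                e_counts.append(len(t))
                exon_lens.extend(lens)
                introns = [t[i + 1][0] - t[i][1] - 1 for i in range(len(t) - 1)]
                pooled_introns.extend(introns)
                if introns:
                    per_t_means.append(float(np.mean(introns)))
            if not ok:
                continue
            rec["transcript_length"] = float(np.mean(t_lengths))
            rec["exon_count"] = float(np.mean(e_counts))
            rec["exon_length"] = float(np.mean(exon_lens))
            src = pooled_introns if intron_mode == "pooled" else per_t_means
            if src:
                rec["intron_length"] = float(np.mean(src))
        rows[gid] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return table[list(FEATURES)]


@dataclass
class FeatureComparison:
    feature: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    p_value: float
    method: str

    @property
    def direction(self) -> str:
        """Which side group A falls on relative to group B."""
        if self.median_a < self.median_b:
            return f"{self.label_a} lower"
        if self.median_a > self.median_b:
            return f"{self.label_a} higher"
        return "equal medians"

    def summary(self) -> dict:
        return {
            "feature": self.feature,
            "groups": [self.label_a, self.label_b],
            "sizes": [self.n_a, self.n_b],
            "medians": [self.median_a, self.median_b],
            "p_value": self.p_value,
            "direction": self.direction,
            "method": self.method,
        }


def compare_groups(
    table: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    feature: str,
    label_a: str = "A",
    label_b: str = "B",
) -> FeatureComparison:
    """Two-sided Wilcoxon rank-sum comparison of one feature between two
    gene groups.

    Genes with an absent value (e.g. intron length of intron-less genes)
    are dropped first.  The exact null distribution is used when both
    groups have <= 20 values and there are no ties; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    """
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    a = table.loc[table.index.intersection(list(group_a)), feature].dropna().to_numpy()
    b = table.loc[table.index.intersection(list(group_b)), feature].dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("a comparison group is empty after dropping absent values")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    exact = a.size <= 20 and b.size <= 20 and no_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return FeatureComparison(
        feature=feature,
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=float(res.pvalue),
        method="exact" if exact else "normal-approximation",
    )


def compare_all_features(
    table: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    label_a: str = "A",
    label_b: str = "B",
) -> list[FeatureComparison]:
    """All six feature contrasts between two gene groups (raw p-values;
    no multiplicity correction)."""
    group_a, group_b = list(group_a), list(group_b)
    out = []
    for feat in FEATURES:
        try:
            out.append(
                compare_groups(table, group_a, group_b, feat, label_a, label_b)
            )
        except ValueError:
            logger.warning("skipping feature %s: empty group", feat)
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_comparisons_tsv(comparisons: list[FeatureComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature\tgroup_a\tgroup_b\tn_a\tn_b\tmedian_a\tmedian_b"
            "\tdirection\tp_value\tmethod\n"
        )
        for c in comparisons:
            fh.write(
                f"{c.feature}\t{c.label_a}\t{c.label_b}\t{c.n_a}\t{c.n_b}"
                f"\t{c.median_a:.12g}\t{c.median_b:.12g}\t{c.direction}"
                f"\t{c.p_value:.6g}\t{c.method}\n"
            )
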