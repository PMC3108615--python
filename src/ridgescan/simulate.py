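"""Synthetic genomes and expression matrices with planted structure.

The generator lays genes along chromosomes and plants one high-expression
(RIDGE-like) and one low-expression (anti-RIDGE-like) gene block per
chromosome, sized so that each kind covers the configured fraction of the
genome in bp (10% by default, the calibration target of the analysis).
Gene structure (exon count, exon/intron lengths, GC) is drawn from
class-conditional distributions so planted-RIDGE genes are stochastically
shorter, more compact and more GC-rich than planted-anti-RIDGE genes —
the contrasts the feature comparison should recover.

Expression is additive on the log2 scale: a background level, a domain
shift of +/- delta inside planted blocks, a class term making HK genes
expressed in every tissue, TS genes in exactly one and silent genes in
none, a shared per-gene random effect inducing between-tissue map
correlation, and Gaussian noise; values are clipped to a plausible
intensity range (default [8, 15], the scale of the arrays the pipeline
was built around).  Negative-control intensities are Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    ANTIRIDGE,
    Annotation,
    DEFAULT_TISSUES,
    ExpressionMatrix,
    GeneModel,
    INTERMEDIATE,
    RIDGE,
)

logger = logging.getLogger("ridgescan")


@dataclass(frozen=True)
class ClassProfile:
    """Structural distribution of one planted gene class."""

    exon_count_mean: float
    exon_length_mean: float
    intron_length_mean: float
    gc_mean: float
    gc_sd: float = 0.04

    def expected_gene_length(self) -> float:
        k = self.exon_count_mean
        return k * self.exon_length_mean + (k - 1) * self.intron_length_mean


#: Default structural contrasts: planted-RIDGE genes are short and compact
#: with high GC; planted-anti-RIDGE genes are long with low GC.
DEFAULT_FEATURE_PROFILE: dict[str, ClassProfile] = {
    RIDGE: ClassProfile(6.0, 250.0, 1800.0, 0.52),
    INTERMEDIATE: ClassProfile(8.0, 270.0, 3200.0, 0.47),
    ANTIRIDGE: ClassProfile(8.0, 280.0, 5200.0, 0.42),
}


@dataclass
class SimParams:
    """Knobs of the simulation; defaults define the reference conditions."""

    coverage_target: float = 0.10
    delta: float = 1.5            # domain shift, log2 units
    mu_bg: float = 11.0           # background log2 intensity
    sigma_bg: float = 0.4         # per-(gene,tissue) noise s.d.
    shared_sd: float = 0.8        # per-gene shared effect -> tissue correlation
    mu_nc: float = 8.7            # negative-control mean
    sigma_nc: float = 0.3
    n_controls: int = 2000
    clip_low: float = 8.0
    clip_high: float = 15.0
    hk_prob_ridge: float = 0.35   # HK placement inside planted RIDGEs ...
    hk_prob_background: float = 0.18  # ... vs elsewhere (over-representation)
    ts_prob: float = 0.08
    silent_prob: float = 0.12
    hk_term: float = 1.6
    ts_on_term: float = 1.2
    ts_off_term: float = -2.0
    silent_term: float = -2.2
    intermediate_low: float = -2.5   # per-gene baseline offset range for
    intermediate_high: float = 0.5   # intermediate genes (spreads n_expressed)
    gap_mean: float = 15000.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_target < 0.5:
            raise ValueError("coverage_target must be in (0, 0.5)")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    intervals: dict[str, list[tuple[int, int, str]]]
    gene_class: dict[str, str]      # HK / TS:<tissue> / intermediate / silent
    gene_domain: dict[str, str]     # RIDGE / ANTIRIDGE / INTERMEDIATE
    coverage: dict[str, float]
    coverage_target: float
    seed: int
    params: SimParams = field(default_factory=SimParams)

    def genes_in_domain(self, kind: str) -> set[str]:
        return {g for g, d in self.gene_domain.items() if d == kind}

    def to_dict(self) -> dict:
        return {
            "intervals": {
                c: [[int(s), int(e), k] for s, e, k in v]
                for c, v in self.intervals.items()
            },
            "gene_class": self.gene_class,
            "gene_domain": self.gene_domain,
            "coverage": self.coverage,
            "coverage_target": self.coverage_target,
            "seed": self.seed,
            "params": asdict(self.params),
        }


def _solve_block_sizes(
    g: int, c: float, spans: Mapping[str, float]
) -> tuple[int, int]:
    """Gene counts for the planted blocks so each kind's expected bp
    coverage equals ``c``.

    With per-class expected spans s_R, s_A, s_B and block counts n_R, n_A:
    n_R s_R = n_A s_A = c T where T is total expected length.
    """
    s_r, s_a, s_b = spans[RIDGE], spans[ANTIRIDGE], spans[INTERMEDIATE]
    denom = 1.0 + c * s_b * (1 / s_r + 1 / s_a) / (1 - 2 * c)
    x = (c * g * s_b / (1 - 2 * c)) / denom  # bp per planted kind
    n_r = max(1, round(x / s_r))
    n_a = max(1, round(x / s_a))
    return n_r, n_a


def _draw_gene_structure(rng, profile: ClassProfile, start: int):
    k = 1 + rng.poisson(max(profile.exon_count_mean - 1, 0.0))
    exon_lens = np.maximum(
        rng.gamma(3.0, profile.exon_length_mean / 3.0, size=k), 30.0
    ).astype(np.int64)
    intron_lens = (
        np.maximum(rng.gamma(2.0, profile.intron_length_mean / 2.0, size=k - 1), 30.0)
        .astype(np.int64)
        if k > 1
        else np.empty(0, dtype=np.int64)
    )
    exons = []
    pos = start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1
        if i < k - 1:
            pos += int(intron_lens[i])
    end = exons[-1][1]
    gc = float(np.clip(rng.normal(profile.gc_mean, profile.gc_sd), 0.25, 0.75))
    return exons, end, gc


def generate_genome(
    n_chrom: int = 3,
    genes_per_chrom: int = 700,
    seed: int = 0,
    feature_profile: Mapping[str, ClassProfile] | None = None,
    params: SimParams | None = None,
) -> tuple[Annotation, SimulationTruth]:
    """Simulate an annotated genome with planted expression domains.

    Each chromosome carries one RIDGE-like and one anti-RIDGE-like gene
    block at a random location; block gene counts are solved from the
    class-conditional expected gene spans so that each kind covers
    approximately ``params.coverage_target`` of the genome in bp.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    params = params or SimParams()
    profile = dict(feature_profile or DEFAULT_FEATURE_PROFILE)
    rng = np.random.default_rng(seed)
    spans = {
        k: p.expected_gene_length() + params.gap_mean for k, p in profile.items()
    }
    n_r, n_a = _solve_block_sizes(genes_per_chrom, params.coverage_target, spans)
    n_bg = genes_per_chrom - n_r - n_a
    if n_bg < 9:  # need three background segments of >= 3 genes
        raise ValueError(
            "planted domains would overlap: not enough background genes "
            f"({genes_per_chrom} genes, blocks {n_r}+{n_a})"
        )

    genes: list[GeneModel] = []
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    gene_domain: dict[str, str] = {}
    gene_class: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    gid_counter = 0

    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        # split background genes into three segments of >= 3 genes each
        free = n_bg - 9
        cut1, cut2 = sorted(rng.integers(0, free + 1, size=2))
        seg = [3 + cut1, 3 + (cut2 - cut1), 3 + (free - cut2)]
        first_up = bool(rng.integers(0, 2))
        blocks = (
            [(seg[0], None), (n_r, RIDGE), (seg[1], None),
             (n_a, ANTIRIDGE), (seg[2], None)]
            if first_up
            else [(seg[0], None), (n_a, ANTIRIDGE), (seg[1], None),
                  (n_r, RIDGE), (seg[2], None)]
        )
        pos = 1
        intervals[chrom] = []
        for count, kind in blocks:
            block_start = None
            block_end = None
            for _ in range(count):
                pos += int(np.maximum(rng.gamma(4.0, params.gap_mean / 4.0), 200.0))
                prof = profile[kind if kind else INTERMEDIATE]
                exons, end, gc = _draw_gene_structure(rng, prof, pos)
                gid = f"G{gid_counter:06d}"
                gid_counter += 1
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        chrom=chrom,
                        start=pos,
                        end=end,
                        strand="+" if rng.integers(0, 2) else "-",
                        transcripts=(tuple(exons),),
                        gc_fraction=gc,
                    )
                )
                gene_domain[gid] = kind if kind else INTERMEDIATE
                in_ridge = kind == RIDGE
                u = rng.random()
                p_hk = params.hk_prob_ridge if in_ridge else params.hk_prob_background
                if u < p_hk:
                    gene_class[gid] = "HK"
                elif u < p_hk + params.ts_prob:
                    tissue = DEFAULT_TISSUES[rng.integers(0, len(DEFAULT_TISSUES))]
                    gene_class[gid] = f"TS:{tissue}"
                elif u < p_hk + params.ts_prob + params.silent_prob:
                    gene_class[gid] = "silent"
                else:
                    gene_class[gid] = "intermediate"
                if block_start is None:
                    block_start = pos
                block_end = max(block_end or 0, end)
                pos = end
            if kind is not None:
                intervals[chrom].append((block_start, block_end, kind))
        pos += int(np.maximum(rng.gamma(4.0, params.gap_mean / 4.0), 200.0))
        chrom_lengths[chrom] = pos

    genome_len = sum(chrom_lengths.values())
    cov = {
        kind: sum(
            e - s + 1 for ivs in intervals.values() for s, e, k in ivs if k == kind
        )
        / genome_len
        for kind in (RIDGE, ANTIRIDGE)
    }
    for kind, c in cov.items():
        if abs(c - params.coverage_target) > 0.1 * params.coverage_target:
            logger.warning(
                "planted %s coverage %.4f misses target %.4f by >10%% relative",
                kind, c, params.coverage_target,
            )
    annotation = Annotation.from_genes(genes, chrom_lengths)
    truth = SimulationTruth(
        intervals=intervals,
        gene_class=gene_class,
        gene_domain=gene_domain,
        coverage=cov,
        coverage_target=params.coverage_target,
        seed=int(seed),
        params=params,
    )
    return annotation, truth


def generate_expression(
    annotation: Annotation,
    truth: SimulationTruth,
    n_tissues: int = 5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate the log2 expression matrix implied by a SimulationTruth.

    value(g, t) = mu_bg + domain shift (+delta in RIDGE, -delta in
    anti-RIDGE) + class term + shared per-gene effect + N(0, sigma_bg),
    clipped to [clip_low, clip_high].  Negative controls are
    N(mu_nc, sigma_nc).
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    missing = set(truth.gene_domain) - set(annotation.genes)
    if missing:
        raise ValueError("truth does not match annotation")
    p = truth.params
    tissues = (
        list(DEFAULT_TISSUES[:n_tissues])
        if n_tissues <= len(DEFAULT_TISSUES)
        else [f"T{i + 1}" for i in range(n_tissues)]
    )
    rng = np.random.default_rng(seed)
    gene_ids = [
        gid for chrom in annotation.index.chromosomes
        for gid in annotation.index.order[chrom]
    ]
    n = len(gene_ids)
    values = np.empty((n, n_tissues), dtype=float)
    shared = rng.normal(0.0, p.shared_sd, size=n)
    inter_offset = rng.uniform(p.intermediate_low, p.intermediate_high, size=n)
    for i, gid in enumerate(gene_ids):
        domain = truth.gene_domain.get(gid, INTERMEDIATE)
        shift = p.delta if domain == RIDGE else (-p.delta if domain == ANTIRIDGE else 0.0)
        cls = truth.gene_class.get(gid, "intermediate")
        if cls == "HK":
            term = np.full(n_tissues, p.hk_term)
        elif cls.startswith("TS:"):
            term = np.full(n_tissues, p.ts_off_term)
            t = cls.split(":", 1)[1]
            if t in tissues:
                term[tissues.index(t)] = p.ts_on_term
            else:  # panel smaller than the truth's tissue: pick first
                term[0] = p.ts_on_term
        elif cls == "silent":
            term = np.full(n_tissues, p.silent_term)
        else:
            term = np.full(n_tissues, inter_offset[i])
        noise = rng.normal(0.0, p.sigma_bg, size=n_tissues)
        values[i] = p.mu_bg + shift + term + shared[i] + noise
    np.clip(values, p.clip_low, p.clip_high, out=values)
    controls = np.clip(
        rng.normal(p.mu_nc, p.sigma_nc, size=p.n_controls), p.clip_low, p.clip_high
    )
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=tissues)
    return ExpressionMatrix(frame, negative_controls=controls)
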