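"""End-to-end pipeline: simulate/load -> map -> calibrate -> call ->
permutation test -> classify -> enrichment -> selection distribution ->
feature contrasts, with a JSON run report.

One global seed expands into independent per-stage substreams
(numpy SeedSequence.spawn), so any stage re-run in isolation with its
substream reproduces its output.  The run report contains only
deterministic quantities; wall-times are logged to stderr.
"""

from __future__ import annotations

import logging
import time
from itertools import combinations
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (
    classify_genes,
    categorize_genes,
    expression_threshold,
    fisher_region_distribution,
    overlap_resampling_test,
)
from .features import compare_all_features, extract_features, write_comparisons_tsv, write_feature_table
from .io import (
    read_annotation,
    read_expression,
    write_annotation_tsv,
    write_expression,
    write_json,
    write_regions_bed,
    write_regions_tsv,
)
from .maps import build_map, map_correlation, write_map_tsv
from .model import PipelineConfig
from .regions import calibrate, call_regions, coverage, genomic_median, permutation_test
from .simulate import SimParams, generate_expression, generate_genome

logger = logging.getLogger("ridgescan")

_STAGES = (
    "sim_genome", "sim_expr", "perm_up", "perm_down",
    "enrich_hk", "enrich_ts", "query",
)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def run_all(
    config: PipelineConfig,
    outdir,
    simulate: bool = False,
    annotation_path=None,
    expression_path=None,
    controls_path=None,
    selected_path=None,
    n_chrom: int = 3,
    genes_per_chrom: int = 700,
    sim_params: SimParams | None = None,
    calibrate_folds: bool = True,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(config.rng_seed)
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                logger.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)

        return _T()

    # ---- inputs ----------------------------------------------------------
    with timed("inputs"):
        if simulate:
            sim_params = sim_params or SimParams()
            annotation, truth = generate_genome(
                n_chrom=n_chrom,
                genes_per_chrom=genes_per_chrom,
                seed=int(rngs["sim_genome"].integers(2**31)),
                params=sim_params,
            )
            expr = generate_expression(
                annotation, truth, seed=int(rngs["sim_expr"].integers(2**31))
            )
            write_annotation_tsv(annotation, outdir / "annotation.tsv")
            write_expression(expr, outdir / "expression.tsv", outdir / "controls.tsv")
            write_json(truth.to_dict(), outdir / "truth.json")
            report["stages"]["inputs"] = {
                "mode": "simulated",
                "n_genes": len(annotation),
                "planted_coverage": truth.coverage,
            }
        else:
            if annotation_path is None or expression_path is None:
                raise FileNotFoundError(
                    "run-all needs --annot and --expr unless --simulate is given"
                )
            annotation = read_annotation(annotation_path)
            expr = read_expression(
                expression_path, annotation=annotation, controls_path=controls_path
            )
            truth = None
            report["stages"]["inputs"] = {
                "mode": "files",
                "n_genes": len(annotation),
                "n_expression_genes": len(expr.genes),
                "n_unmapped": len(expr.unmapped_genes),
            }

    # ---- maps + correlation ---------------------------------------------
    with timed("map"):
        avg_map = build_map(expr, annotation, tissue="average", window=config.window)
        write_map_tsv(avg_map, outdir / "map_average.tsv")
        tissue_maps = {
            t: build_map(expr, annotation, tissue=t, window=config.window)
            for t in expr.tissues
        }
    with timed("correlate"):
        correlations = {}
        for a, b in combinations(expr.tissues, 2):
            rho, p = map_correlation(tissue_maps[a], tissue_maps[b])
            correlations[f"{a}~{b}"] = {"rho": rho, "p": p}
        mean_rho = float(np.mean([v["rho"] for v in correlations.values()])) \
            if correlations else float("nan")
        report["stages"]["correlate"] = {
            "pairwise": correlations, "mean_rho": mean_rho,
        }

    # ---- calibration + region calling -----------------------------------
    with timed("call"):
        m = genomic_median(avg_map)
        folds = {"up": config.fold_up, "down": config.fold_down}
        calib_info = {}
        if calibrate_folds:
            for direction in ("up", "down"):
                res = calibrate(
                    avg_map, direction,
                    target=config.coverage_target,
                    grid_step=config.grid_step,
                    fold_max=config.fold_max,
                    min_stretch=config.min_stretch,
                    m=m,
                )
                folds[direction] = res.fold
                calib_info[direction] = {
                    "fold": res.fold, "coverage": res.coverage,
                }
        ridges = call_regions(
            avg_map, m, folds["up"], "up", config.min_stretch, annotation
        )
        antiridges = call_regions(
            avg_map, m, folds["down"], "down", config.min_stretch, annotation
        )
        regions = ridges + antiridges
        write_regions_bed(regions, outdir / "regions.bed")
        write_regions_tsv(regions, outdir / "regions.tsv")
        report["stages"]["call"] = {
            "genomic_median": m,
            "folds": folds,
            "calibration": calib_info,
            "n_ridges": len(ridges),
            "n_antiridges": len(antiridges),
            "n_ridge_genes": len({g for r in ridges for g in r.member_genes}),
            "n_antiridge_genes": len({g for r in antiridges for g in r.member_genes}),
            "coverage_ridge": coverage(ridges, avg_map.chrom_lengths),
            "coverage_antiridge": coverage(antiridges, avg_map.chrom_lengths),
        }

    # ---- permutation null ------------------------------------------------
    with timed("permtest"):
        perm = {}
        for direction, rng_name in (("up", "perm_up"), ("down", "perm_down")):
            null = permutation_test(
                expr, annotation, config, direction,
                seed=rngs[rng_name], fold=folds[direction],
            )
            perm[direction] = null.summary()
        write_json(perm, outdir / "permutation.json")
        report["stages"]["permtest"] = perm

    # ---- classification --------------------------------------------------
    with timed("classify"):
        if len(expr.negative_controls) == 0:
            raise ValueError("no negative-control intensities available")
        tau = expression_threshold(expr.negative_controls, config.control_quantile)
        classification = classify_genes(expr, tau)
        classification.table.to_csv(outdir / "classes.tsv", sep="\t")
        report["stages"]["classify"] = {
            "threshold": tau,
            "class_counts": classification.class_counts(),
        }

    # ---- enrichment on RIDGE genes --------------------------------------
    with timed("enrich"):
        universe = [g for g in expr.genes if g in annotation.genes]
        ridge_genes = {g for r in ridges for g in r.member_genes} & set(universe)
        enrich = {}
        for label, rng_name in (("HK", "enrich_hk"), ("TS", "enrich_ts")):
            query = classification.genes_with_label(label) & set(universe)
            if query and ridge_genes:
                res = overlap_resampling_test(
                    query, ridge_genes, universe,
                    n_samp=config.n_samp, seed=rngs[rng_name],
                )
                enrich[label] = res.summary()
            else:
                enrich[label] = {"skipped": "empty query or no RIDGE genes"}
        write_json(enrich, outdir / "enrichment.json")
        report["stages"]["enrich"] = enrich

    # ---- region distribution of a query gene list ------------------------
    with timed("seldist"):
        if selected_path is not None:
            with open(selected_path) as fh:
                query_genes = [ln.strip() for ln in fh if ln.strip()]
        elif simulate:
            # demonstration query under the null: a random draw of genes
            query_genes = list(
                rngs["query"].choice(universe, size=min(54, len(universe)),
                                     replace=False)
            )
        else:
            query_genes = []
        if query_genes:
            background = categorize_genes(annotation, universe, regions)
            query_cats = {g: background[g] for g in query_genes if g in background}
            dist = fisher_region_distribution(query_cats, background)
            report["stages"]["seldist"] = dist.summary()
            write_json(dist.summary(), outdir / "selection_distribution.json")
        else:
            report["stages"]["seldist"] = {"skipped": "no query gene list"}

    # ---- genomic features ------------------------------------------------
    with timed("features"):
        table = extract_features(annotation)
        write_feature_table(table, outdir / "features.tsv")
        ridge_members = {g for r in ridges for g in r.member_genes}
        anti_members = {g for r in antiridges for g in r.member_genes}
        comparisons = []
        feat_report = {}
        if ridge_members and anti_members:
            comp = compare_all_features(
                table, ridge_members, anti_members, "RIDGE", "anti-RIDGE"
            )
            comparisons += comp
            feat_report["RIDGE_vs_antiRIDGE"] = [c.summary() for c in comp]
        hk = classification.genes_with_label("HK")
        ts = classification.genes_with_label("TS")
        if hk and ts:
            comp = compare_all_features(table, hk, ts, "HK", "TS")
            comparisons += comp
            feat_report["HK_vs_TS"] = [c.summary() for c in comp]
        write_comparisons_tsv(comparisons, outdir / "feature_comparisons.tsv")
        report["stages"]["features"] = feat_report

    write_json(report, outdir / "report.json")
    return report
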