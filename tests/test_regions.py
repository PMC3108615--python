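import numpy as np
import pytest

from ridgescan import (
    Annotation,
    GeneModel,
    PipelineConfig,
    calibrate,
    call_regions,
    coverage,
    genomic_median,
    permutation_test,
)
from conftest import make_map


@pytest.mark.parametrize(
    "values,expected",
    [([9, 10, 11], 10.0), ([9, 10, 11, 12], 10.5), ([11, 11, 11], 11.0)],
)
def test_genomic_median(values, expected):
    assert genomic_median(make_map(values)) == expected


def test_single_ridge_from_twelve_consecutive_positions():
    smoothed = [10.0] * 20 + [13.0] * 12 + [10.0] * 20
    tmap = make_map(smoothed)
    regions = call_regions(tmap, 10.0, 1.2, "up", 10)
    assert len(regions) == 1
    r = regions[0]
    assert r.n_gene_positions == 12
    assert r.kind == "RIDGE"
    # spans the qualifying genes exactly (1000 bp each, genes 20..31)
    assert (r.start, r.end) == (20 * 1000 + 1, 32 * 1000)


def test_run_shorter_than_min_stretch_gives_no_region():
    smoothed = [10.0] * 20 + [13.0] * 8 + [10.0] * 20
    assert call_regions(make_map(smoothed), 10.0, 1.2, "up", 10) == []


def test_threshold_ties_do_not_qualify():
    tmap = make_map([10.0] * 40)
    assert call_regions(tmap, 10.0, 1.2, "up", 10) == []
    assert call_regions(tmap, 10.0, 1.2, "down", 10) == []


def test_down_direction_uses_division():
    smoothed = [10.0] * 15 + [6.0] * 11 + [10.0] * 15
    regions = call_regions(make_map(smoothed), 10.0, 1.45, "down", 10)
    assert len(regions) == 1
    assert regions[0].kind == "ANTIRIDGE"
    # 6.0 < 10/1.45 = 6.897 qualifies; 10.0 does not
    assert regions[0].n_gene_positions == 11


def test_regions_disjoint_and_separated():
    smoothed = [13.0] * 12 + [10.0] + [13.0] * 12 + [10.0] * 30
    regions = call_regions(make_map(smoothed), 10.0, 1.2, "up", 10)
    assert len(regions) == 2
    a, b = sorted(regions, key=lambda r: r.start)
    assert a.end < b.start  # disjoint, separated by the non-qualifying gene


def test_member_genes_any_overlap_rule():
    # annotation gene overlapping the region interval by 1 bp is a member
    genes = [
        GeneModel("in1", "chr1", 20 * 1000 + 1, 20 * 1000 + 500),
        GeneModel("edge", "chr1", 31 * 1000 + 999, 33 * 1000),  # 2 bp overlap
        GeneModel("out", "chr1", 40 * 1000, 41 * 1000),
    ]
    ann = Annotation.from_genes(genes, {"chr1": 52_000})
    smoothed = [10.0] * 20 + [13.0] * 12 + [10.0] * 20
    regions = call_regions(make_map(smoothed), 10.0, 1.2, "up", 10, annotation=ann)
    assert set(regions[0].member_genes) == {"in1", "edge"}


def test_member_genes_cover_qualifying_run(small_simulation):
    annotation, _, expr = small_simulation
    from ridgescan import build_map

    tmap = build_map(expr, annotation, "average", 39)
    m = genomic_median(tmap)
    regions = call_regions(tmap, m, 1.1, "up", 10, annotation=annotation)
    assert regions
    for r in regions:
        cm = tmap.chroms[r.chrom]
        run_genes = {
            g for g, s, e in zip(cm.gene_ids, cm.positions, cm.gene_ends)
            if s >= r.start and e <= r.end
        }
        assert run_genes <= set(r.member_genes)


class TestCoverage:
    def test_examples(self):
        from ridgescan.model import RegionCall

        r10 = RegionCall("chr1", 1, 10_000_000, "RIDGE", 10)
        assert coverage([r10], {"chr1": 100_000_000}) == pytest.approx(0.10)
        assert coverage([], {"chr1": 100_000_000}) == 0.0
        r3 = RegionCall("chr1", 1, 3_000_000, "RIDGE", 10)
        r7 = RegionCall("chr2", 1, 7_000_000, "RIDGE", 10)
        assert coverage([r3, r7], {"chr1": 50_000_000, "chr2": 50_000_000}) == (
            pytest.approx(0.10)
        )

    def test_invariant_under_chromosome_relabeling(self):
        from ridgescan.model import RegionCall

        regions = [RegionCall("chrA", 1, 500, "RIDGE", 10)]
        relabeled = [RegionCall("chrB", 1, 500, "RIDGE", 10)]
        lengths_a = {"chrA": 1000, "chrB": 9000}
        lengths_b = {"chrB": 1000, "chrA": 9000}
        assert coverage(regions, lengths_a) == coverage(relabeled, lengths_b)

    def test_zero_genome_length_errors(self):
        with pytest.raises(ValueError):
            coverage([], {})


class TestCalibrate:
    def test_coverage_monotone_decreasing_in_fold(self, small_simulation):
        annotation, _, expr = small_simulation
        from ridgescan import build_map

        tmap = build_map(expr, annotation, "average", 39)
        res = calibrate(tmap, "up", 0.10)
        folds = sorted(res.curve)
        covs = [res.curve[f] for f in folds]
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_constructed_curve_picks_closest_fold(self):
        # 100 genes of 1 kb: 13 at a level qualifying up to fold 1.26,
        # 10 more qualifying up to 1.21, another 10 up to 1.16 ->
        # coverage(1.05..1.15)=0.33, (1.20)=0.23, (1.25)=0.13, (1.30)=0
        smoothed = (
            [10.0] * 20 + [12.7] * 13 + [10.0] * 12 + [12.2] * 10
            + [10.0] * 12 + [11.7] * 10 + [10.0] * 23
        )
        tmap = make_map(smoothed)
        res = calibrate(tmap, "up", target=0.10, min_stretch=10)
        assert res.fold == pytest.approx(1.25)
        assert res.coverage == pytest.approx(0.13)

    def test_optimal_on_grid(self, small_simulation):
        annotation, _, expr = small_simulation
        from ridgescan import build_map

        tmap = build_map(expr, annotation, "average", 39)
        for direction in ("up", "down"):
            res = calibrate(tmap, direction, 0.10)
            best_err = abs(res.coverage - 0.10)
            assert all(
                best_err <= abs(c - 0.10) + 1e-12 for c in res.curve.values()
            )

    def test_target_one_like_means_smallest_fold(self):
        # five 10-gene blocks at staggered levels: coverage strictly
        # decreases with fold, so a near-1 target selects the smallest fold
        levels = [10.51, 11.01, 11.51, 12.01, 12.51]
        smoothed = []
        for lv in levels:
            smoothed += [lv] * 10 + [10.0] * 5
        smoothed += [10.0] * 25
        res = calibrate(make_map(smoothed), "up", target=0.999, min_stretch=10)
        assert res.fold == pytest.approx(1.05)

    def test_all_zero_coverage_warns_and_returns_smallest(self, caplog):
        tmap = make_map([10.0] * 50)
        with caplog.at_level("WARNING", logger="ridgescan"):
            res = calibrate(tmap, "up", 0.10)
        assert res.fold == pytest.approx(1.05)
        assert any("zero coverage" in r.message for r in caplog.records)

    def test_tie_breaks_to_larger_fold(self):
        # no region at any fold below the step where coverage drops 0.2 -> 0:
        # folds with equal |cov - target| resolve to the more stringent one
        smoothed = [12.0] * 20 + [10.0] * 80
        tmap = make_map(smoothed)
        res = calibrate(tmap, "up", target=0.10, min_stretch=10)
        curve = res.curve
        best = abs(curve[res.fold] - 0.10)
        ties = [f for f, c in curve.items() if abs(c - 0.10) == best]
        assert res.fold == max(ties)


class TestPermutation:
    def test_constant_expression_p_one(self, toy_annotation):
        import pandas as pd
        from ridgescan import ExpressionMatrix

        genes = list(toy_annotation.genes)
        expr = ExpressionMatrix(
            pd.DataFrame(10.0, index=genes, columns=["AP", "AM"]),
            negative_controls=[9.0],
        )
        cfg = PipelineConfig(window=3, min_stretch=2, n_perm=20, rng_seed=1)
        null = permutation_test(expr, toy_annotation, cfg, "up", seed=1)
        assert null.observed == 0
        assert np.all(null.values == 0)
        assert null.p_empirical == 1.0

    def test_null_summaries_recomputable_from_values(self, small_simulation):
        annotation, _, expr = small_simulation
        cfg = PipelineConfig(n_perm=30, rng_seed=5)
        null = permutation_test(expr, annotation, cfg, "up", seed=5, fold=1.1)
        assert null.mean == pytest.approx(np.mean(null.values))
        assert null.sd == pytest.approx(np.std(null.values, ddof=1))
        tail = np.sum(null.values >= null.observed)
        assert null.p_empirical == pytest.approx((tail + 1) / (len(null.values) + 1))
        assert null.p_plain == pytest.approx(tail / len(null.values))

    def test_n_perm_below_one_errors(self, small_simulation):
        annotation, _, expr = small_simulation
        cfg = PipelineConfig(rng_seed=0)
        with pytest.raises(ValueError):
            permutation_test(expr, annotation, cfg, "up", n_perm=0)
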