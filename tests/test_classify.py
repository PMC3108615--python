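import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ridgescan import (
    ExpressionMatrix,
    classify_genes,
    expression_threshold,
    fisher_region_distribution,
    overlap_resampling_test,
)
from ridgescan.classify import (
    assign_region_category,
    fisher_exact_2xc,
    hypergeometric_overlap_sd,
)
from ridgescan.model import RegionCall

TISSUES = ["AP", "AM", "HC", "DH", "VH"]


def _matrix(rows: dict):
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)
    )


class TestThreshold:
    def test_constant_controls(self):
        assert expression_threshold([7.5] * 40, 0.999) == 7.5

    def test_linear_interpolation_formula(self):
        # sorted x(1..n), h=(n-1)q+1: controls 1..1000, q=0.999 -> 999.001
        assert expression_threshold(np.arange(1, 1001), 0.999) == pytest.approx(
            999.001
        )

    def test_median_equivalence(self):
        assert expression_threshold([1, 2, 3], 0.5) == 2.0

    def test_empty_controls_error(self):
        with pytest.raises(ValueError):
            expression_threshold([], 0.999)


class TestClassifier:
    def test_hk_ts_intermediate_silent(self):
        expr = _matrix({
            "hk": [12, 12, 12, 12, 12],
            "ts_ap": [12, 9, 9, 9, 9],
            "mid": [12, 12, 9, 9, 9],
            "off": [9, 9, 9, 9, 9],
        })
        cls = classify_genes(expr, 10.0)
        labels = cls.table["label"]
        assert labels["hk"] == "HK"
        assert labels["ts_ap"] == "TS:AP"
        assert labels["mid"] == "intermediate"
        assert labels["off"] == "silent"
        assert cls.table.loc["mid", "n_expressed"] == 2

    def test_partition_sums_to_total(self, small_simulation):
        _, _, expr = small_simulation
        tau = expression_threshold(expr.negative_controls, 0.999)
        cls = classify_genes(expr, tau)
        assert sum(cls.class_counts().values()) == len(expr.genes)

    def test_strictly_above_threshold(self):
        expr = _matrix({"g": [10.0, 10.0, 10.0, 10.0, 10.0]})
        assert classify_genes(expr, 10.0).table.loc["g", "n_expressed"] == 0

    @given(st.floats(8, 15), st.floats(0, 3))
    @settings(max_examples=100, deadline=None)
    def test_raising_threshold_never_raises_counts(self, tau, bump):
        rng = np.random.default_rng(7)
        expr = _matrix({f"g{i}": rng.uniform(8, 15, 5) for i in range(20)})
        lo = classify_genes(expr, tau).table["n_expressed"]
        hi = classify_genes(expr, tau + bump).table["n_expressed"]
        assert (hi <= lo).all()


class TestOverlapResampling:
    def test_region_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(50)]
        res = overlap_resampling_test(universe[:10], universe, universe,
                                      n_samp=200, seed=0)
        assert res.observed_percent == 100.0
        assert res.null.sd == 0.0
        assert np.all(res.null.values == 100.0)

    def test_null_sd_matches_hypergeometric_closed_form(self):
        universe = [f"g{i}" for i in range(2000)]
        region = set(universe[:400])  # p = 0.2
        query = universe[-300:]
        res = overlap_resampling_test(query, region, universe,
                                      n_samp=4000, seed=3)
        exact = hypergeometric_overlap_sd(300, 2000, 0.2)
        # s.d. of a sample s.d.: sigma/sqrt(2B)
        assert abs(res.null.sd - exact) < 3 * exact / math.sqrt(2 * 4000)

    def test_null_mean_approaches_region_fraction(self):
        universe = [f"g{i}" for i in range(1000)]
        region = set(universe[:175])
        res = overlap_resampling_test(universe[:250], region, universe,
                                      n_samp=4000, seed=4)
        expected = 100 * 175 / 1000
        se = res.null.sd / math.sqrt(4000)
        assert abs(res.null.mean - expected) < 3 * se + 1e-9

    def test_depletion_direction_uses_lower_tail(self):
        universe = [f"g{i}" for i in range(200)]
        region = set(universe[:100])
        query = universe[150:]  # no overlap: clearly depleted
        res = overlap_resampling_test(query, region, universe, n_samp=500, seed=5)
        assert res.direction == "depletion"
        assert res.p_empirical <= 0.05

    def test_query_larger_than_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_resampling_test(["a", "b"], [], ["a"], n_samp=10, seed=0)


class TestRegionCategory:
    REGIONS = [
        RegionCall("chr1", 100, 400, "RIDGE", 10),
        RegionCall("chr1", 1000, 2000, "ANTIRIDGE", 10),
    ]

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (150, 250, "RIDGE"),       # containment
            (390, 450, "RIDGE"),       # partial overlap
            (500, 600, "INTERMEDIATE"),
            (2000, 2400, "ANTIRIDGE"),  # 1 bp overlap
        ],
    )
    def test_assignment(self, start, end, expected):
        assert assign_region_category(start, end, "chr1", self.REGIONS) == expected

    def test_chromosome_without_regions_is_intermediate(self):
        assert (
            assign_region_category(1, 100, "chrUn", self.REGIONS) == "INTERMEDIATE"
        )


def brute_force_fisher_2xc(table):
    """Oracle: enumerate every table with the observed margins via
    itertools, summing point probabilities <= the observed one."""
    table = np.asarray(table, dtype=int)
    col = table.sum(axis=0)
    r1 = table[0].sum()

    def prob(row):
        return math.prod(math.comb(c, x) for c, x in zip(col, row)) / math.comb(
            int(col.sum()), int(r1)
        )

    p_obs = prob(table[0])
    total = 0.0
    ranges = [range(min(c, r1) + 1) for c in col]
    for row in itertools.product(*ranges):
        if sum(row) != r1:
            continue
        p = prob(row)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestFisher:
    def test_two_by_two_enumeration_example(self):
        assert fisher_exact_2xc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_small_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            ncol = int(rng.integers(2, 4))
            table = rng.integers(0, 8, size=(2, ncol))
            while table.sum() > 40 or table.sum() == 0:
                table = rng.integers(0, 8, size=(2, ncol))
            if table.sum(axis=1).min() == 0:
                continue
            got = fisher_exact_2xc(table)
            assert got == pytest.approx(brute_force_fisher_2xc(table), abs=1e-10)

    def test_row_swap_symmetry(self):
        t = np.array([[5, 1, 3], [2, 6, 4]])
        assert fisher_exact_2xc(t) == pytest.approx(fisher_exact_2xc(t[::-1]))

    def test_proportional_rows_p_near_one(self):
        t = [[30, 10, 60], [60, 20, 120]]
        assert fisher_exact_2xc(t) > 0.9

    def test_degenerate_margins_p_one(self, caplog):
        with caplog.at_level("WARNING", logger="ridgescan"):
            assert fisher_exact_2xc([[0, 0], [3, 4]]) == 1.0

    def test_region_distribution_counts_and_collapse(self):
        query = {"a": "RIDGE", "b": "RIDGE", "c": "INTERMEDIATE"}
        background = dict(query)
        background.update({f"x{i}": "INTERMEDIATE" for i in range(10)})
        background.update({f"y{i}": "ANTIRIDGE" for i in range(5)})
        res = fisher_region_distribution(query, background)
        assert res.query_counts == {"RIDGE": 2, "ANTIRIDGE": 0, "INTERMEDIATE": 1}
        assert sum(res.query_counts.values()) == 3
        assert 0 < res.p_value <= 1
        assert 0 < res.p_value_2x2 <= 1
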