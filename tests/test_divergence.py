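import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scdiverge import (AnalysisConfig, classify_divergent, divergence_table,
                       divergence_table_from_moments, divergence_test,
                       match_controls, table2_fixture)
from scdiverge.quantify import ExpressionMatrix


def _expr(values: np.ndarray) -> ExpressionMatrix:
    df = pd.DataFrame(values,
                      index=[f"G{i}" for i in range(values.shape[0])],
                      columns=[f"c{i}" for i in range(values.shape[1])])
    return ExpressionMatrix(rpkm=df, library_sizes=pd.Series(1.0, df.columns))


def _gaussian_table(n_genes, n_cells, mean=10.0, cv=0.7, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, cv * mean, size=(n_genes, n_cells))
    return divergence_table(_expr(x), min_mean_rpkm=0.001)


class TestDivergenceTable:
    def test_cv_definition(self):
        x = np.array([[1.0, 2.0, 3.0, 6.0]])
        t = divergence_table(_expr(x))
        assert t.at["G0", "mean"] == pytest.approx(3.0)
        assert t.at["G0", "sd"] == pytest.approx(np.std(x, ddof=1))
        assert t.at["G0", "cv"] == pytest.approx(np.std(x, ddof=1) / 3.0)

    def test_constant_gene_cv_zero_and_all_zero_undefined(self):
        t = divergence_table(_expr(np.array([[5.0, 5.0, 5.0], [0.0, 0.0, 0.0]])))
        assert t.at["G0", "cv"] == 0.0
        assert np.isnan(t.at["G1", "cv"])

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            divergence_table(_expr(np.array([[1.0]])))

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 5, size=(20, 30))
        a = divergence_table(_expr(x))["cv"]
        b = divergence_table(_expr(x * 37.5))["cv"]
        assert np.allclose(a, b)

    def test_published_worked_example_cv_ratio(self):
        # EGFR relative divergence: 1.8-fold narrower in the line carrying
        # the driver mutation than in the parental comparison line
        fx = table2_fixture()
        cv = {line: sd / mean for line, (mean, sd) in fx["EGFR"].items()}
        assert round(cv["LC2/ad"] / cv["PC-9"], 1) == 1.8

    def test_from_moments(self):
        fx = table2_fixture()
        means = pd.Series({g: fx[g]["PC-9"][0] for g in fx})
        sds = pd.Series({g: fx[g]["PC-9"][1] for g in fx})
        t = divergence_table_from_moments(means, sds, n_cells=46)
        assert t.at["EGFR", "cv"] == pytest.approx(34 / 56)
        assert t.at["RET", "low_expression"]


class TestMatchControls:
    @pytest.fixture()
    def table(self):
        means = pd.Series([1.0, 1.5, 2.0, 3.9, 4.0, 8.0, 100.0],
                          index=list("ABCDEFG"))
        return pd.DataFrame({"mean": means, "sd": means, "cv": 1.0,
                             "n_cells": 50, "low_expression": False})

    def test_two_fold_window_closed(self, table):
        # gene C (mean 2): window [1, 4] closed -> A, B, D and E (4.0 on edge)
        assert set(match_controls("C", table)) == {"A", "B", "D", "E"}

    def test_window_of_one(self, table):
        assert match_controls("G", table, fold_window=1.5) == []

    def test_subsampling_cap_and_determinism(self):
        means = pd.Series(np.linspace(5, 9.9, 1501),
                          index=[f"G{i}" for i in range(1501)])
        table = pd.DataFrame({"mean": means, "cv": 1.0, "n_cells": 50,
                              "low_expression": False})
        a = match_controls("G0", table, max_controls=1000, rng=42)
        b = match_controls("G0", table, max_controls=1000, rng=42)
        assert len(a) == 1000 and a == b
        assert "G0" not in a

    def test_zero_mean_rejected(self, table):
        table.loc["A", "mean"] = 0.0
        with pytest.raises(ValueError, match="zero mean"):
            match_controls("A", table)


class TestDivergenceTest:
    def test_f_equal_to_median_gives_p_one(self):
        table = pd.DataFrame({
            "mean": 10.0, "cv": [0.5] + [0.4, 0.5, 0.6] * 10,
            "n_cells": 50, "low_expression": False,
        }, index=[f"G{i}" for i in range(31)])
        p, _ = divergence_test("G0", [f"G{i}" for i in range(1, 31)], table)
        assert p == pytest.approx(1.0)

    def test_matches_f_distribution_arithmetic(self):
        cvs = [1.2] + list(np.linspace(0.3, 0.7, 20))
        table = pd.DataFrame({"mean": 10.0, "cv": cvs, "n_cells": 26,
                              "low_expression": False},
                             index=[f"G{i}" for i in range(21)])
        controls = [f"G{i}" for i in range(1, 21)]
        p, direction = divergence_test("G0", controls, table)
        F = 1.2 ** 2 / np.median(np.array(cvs[1:]) ** 2)
        expected = 2 * min(stats.f.sf(F, 25, 25), stats.f.cdf(F, 25, 25))
        assert direction == "more"
        assert p == pytest.approx(expected)

    def test_needs_enough_controls(self):
        table = pd.DataFrame({"mean": 10.0, "cv": 0.5, "n_cells": 50,
                              "low_expression": False}, index=["A", "B", "C"])
        with pytest.raises(ValueError, match="controls"):
            divergence_test("A", ["B", "C"], table)

    def test_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2, 5, size=(40, 30))
        t1 = divergence_table(_expr(x))
        t2 = divergence_table(_expr(x[:, rng.permutation(30)]))
        controls = [f"G{i}" for i in range(1, 40)]
        p1, d1 = divergence_test("G0", controls, t1)
        p2, d2 = divergence_test("G0", controls, t2)
        assert d1 == d2 and p1 == pytest.approx(p2)

    def test_null_calibration(self):
        # identically distributed genes: the rejection rate at alpha=0.05
        # should sit near, and not above double, the nominal level
        table = _gaussian_table(n_genes=2000, n_cells=50, seed=10)
        calls = classify_divergent(table, AnalysisConfig(min_mean_rpkm=0.001))
        rate = (calls.results["p"] < 0.05).mean()
        assert 0.02 <= rate <= 0.10

    def test_planted_inflated_sd_detected(self):
        # genes with 3x the background SD at matched mean are called "more"
        rng = np.random.default_rng(3)
        n_cells, n_bg, n_planted = 50, 1000, 100
        bg = rng.normal(10, 2, size=(n_bg, n_cells))
        planted = rng.normal(10, 6, size=(n_planted, n_cells))
        x = np.abs(np.vstack([bg, planted]))
        table = divergence_table(_expr(x), min_mean_rpkm=0.001)
        hits = 0
        for i in range(n_bg, n_bg + n_planted):
            gene = f"G{i}"
            controls = match_controls(gene, table, rng=0)
            controls = [c for c in controls if int(c[1:]) < n_bg]
            p, direction = divergence_test(gene, controls, table)
            hits += (p < 0.05) and (direction == "more")
        assert hits >= 0.9 * n_planted


class TestClassify:
    def test_null_lists_near_alpha(self):
        table = _gaussian_table(n_genes=600, n_cells=50, seed=4)
        calls = classify_divergent(table, AnalysisConfig(min_mean_rpkm=0.001))
        n_called = len(calls.more_diverse) + len(calls.less_diverse)
        assert n_called <= 0.10 * len(table)

    def test_alpha_zero_empty(self):
        table = _gaussian_table(n_genes=200, n_cells=30, seed=5)
        calls = classify_divergent(table, AnalysisConfig(min_mean_rpkm=0.001),
                                   alpha=0.0)
        assert calls.more_diverse == [] and calls.less_diverse == []

    def test_deterministic_with_seed(self):
        table = _gaussian_table(n_genes=300, n_cells=30, seed=6)
        cfg = AnalysisConfig(min_mean_rpkm=0.001, seed=9)
        a = classify_divergent(table, cfg)
        b = classify_divergent(table, cfg)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_percentile_method_agrees_on_gross_effects(self):
        rng = np.random.default_rng(8)
        x = np.abs(np.vstack([rng.normal(10, 2, (200, 50)),
                              rng.normal(10, 10, (1, 50))]))
        table = divergence_table(_expr(x), min_mean_rpkm=0.001)
        for method in ("f", "percentile"):
            calls = classify_divergent(
                table, AnalysisConfig(min_mean_rpkm=0.001), method=method)
            assert "G200" in calls.more_diverse
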