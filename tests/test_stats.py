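"""Statistical layer against closed-form values and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from germquant.stats import (
    CFUSeries,
    adjust_pvalues,
    anova_oneway,
    auc,
    compare_survival_auc,
    fisher_exact,
    normalize_cfu,
    read_cfu_table,
    stress_survival,
    write_cfu_table,
)


def series(cfu, days=None, condition="c", rep=0):
    cfu = list(cfu)
    days = list(days) if days is not None else list(range(0, 10 * len(cfu), 10))
    return CFUSeries(condition, rep, np.array(days, float), np.array(cfu, float))


class TestNormalize:
    def test_examples(self):
        assert list(normalize_cfu(series([200, 100, 50])).normalized) == [1.0, 0.5, 0.25]
        assert list(normalize_cfu(series([50], days=[0])).normalized) == [1.0]

    def test_zero_start_errors(self):
        with pytest.raises(ValueError):
            normalize_cfu(series([0, 10]))


class TestAUC:
    def test_trapezoid_examples(self):
        assert auc(normalize_cfu(series([200, 100, 50], [0, 10, 20]))) == pytest.approx(11.25)
        assert auc(normalize_cfu(series([7, 7], [0, 30]))) == pytest.approx(30.0)
        assert auc(normalize_cfu(series([10, 0], [0, 10]))) == pytest.approx(5.0)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            auc(normalize_cfu(series([10], days=[0])))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        st.floats(0.1, 10.0),
    )
    def test_auc_linear_in_curve(self, fracs, scale):
        days = np.arange(len(fracs)) * 10.0
        s1 = CFUSeries("c", 0, days, np.array(fracs), normalized=np.array(fracs))
        s2 = CFUSeries(
            "c", 0, days, np.array(fracs), normalized=np.array(fracs) * scale
        )
        assert auc(s2) == pytest.approx(scale * auc(s1), rel=1e-9)


class TestCompareAUC:
    def test_identical_groups(self):
        g = [normalize_cfu(series([100, 50], rep=i)) for i in range(3)]
        res = compare_survival_auc(g, [normalize_cfu(series([100, 50], rep=i)) for i in range(3)])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_distinct_means(self):
        a = [normalize_cfu(series([100, 100], rep=i)) for i in range(3)]
        b = [normalize_cfu(series([100, 25], rep=i)) for i in range(3)]
        res = compare_survival_auc(a, b)
        assert res.p_value == 0.0
        assert "degenerate" in res.note

    def test_too_few_replicates(self):
        g = [normalize_cfu(series([100, 50]))]
        with pytest.raises(ValueError):
            compare_survival_auc(g, g)

    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(5)
        a = [normalize_cfu(series(100 * rng.uniform(0.3, 1, 4), rep=i)) for i in range(4)]
        b = [normalize_cfu(series(100 * rng.uniform(0.2, 0.9, 4), rep=i)) for i in range(4)]
        res = compare_survival_auc(a, b)
        ref = sps.ttest_ind([auc(s) for s in a], [auc(s) for s in b])
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        # exhaustive enumeration gives 2 / C(20, 10)
        expected = 2.0 / math.comb(20, 10)
        assert fisher_exact([[10, 0], [0, 10]]).p_value == pytest.approx(expected, rel=1e-12)

    def test_matches_comb_enumeration_small_sweep(self):
        """Every table with margins <= 12 against an independent math.comb
        enumeration oracle (the full <=30 sweep runs in the acceptance suite)."""
        worst = 0.0
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                n = r1 + r2
                for c1 in range(1, min(n, 13)):
                    if not 1 <= n - c1 <= 12:
                        continue
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    denom = math.comb(n, c1)
                    pmf = [
                        math.comb(r1, a) * math.comb(r2, c1 - a) / denom
                        for a in range(lo, hi + 1)
                    ]
                    for a in range(lo, hi + 1):
                        oracle = min(
                            sum(q for q in pmf if q <= pmf[a - lo] * (1 + 1e-12)), 1.0
                        )
                        p = fisher_exact([[a, r1 - a], [c1 - a, r2 - (c1 - a)]]).p_value
                        worst = max(worst, abs(p - oracle))
        assert worst < 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_transpose_symmetry(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p1 = fisher_exact([[a, b], [c, d]]).p_value
        p2 = fisher_exact([[a, c], [b, d]]).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])  # empty margin


class TestANOVA:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        a = rng.normal(400, 40, 25)
        b = rng.normal(430, 40, 30)
        res = anova_oneway([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t**2, rel=1e-9)

    def test_identical_groups_degenerate(self):
        res = anova_oneway([[5.0, 5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert "degenerate" in res.note

    def test_separated_groups_tiny_p(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        assert res.p_value < 1e-6

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestStress:
    def test_quarter_survival(self):
        out = stress_survival([400.0], [100.0])
        assert out["percent_survival"][0] == 25.0

    def test_equal_counts_full_survival(self):
        assert stress_survival([300.0], [300.0])["mean"] == 100.0

    def test_mean_and_sd(self):
        out = stress_survival([100.0, 100.0, 100.0], [50.0, 60.0, 70.0])
        assert out["mean"] == pytest.approx(60.0)
        assert out["sd"] == pytest.approx(10.0)
        assert out["n"] == 3

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            stress_survival([100.0, 0.0], [50.0, 10.0])


class TestAdjust:
    def test_methods(self):
        p = np.array([0.01, 0.04, 0.03])
        assert np.array_equal(adjust_pvalues(p, "none"), p)
        assert np.allclose(adjust_pvalues(p, "bonferroni"), [0.03, 0.12, 0.09])
        bh = adjust_pvalues(p, "bh")
        assert np.all(bh >= p) and np.all(bh <= 1.0)


class TestCfuCsv:
    def test_roundtrip(self, tmp_path):
        rows = [series([100, 60, 30], condition="warm", rep=i) for i in range(2)]
        rows += [series([100, 90, 85], condition="cold", rep=i) for i in range(2)]
        p = tmp_path / "cfu.csv"
        write_cfu_table(rows, p)
        back = read_cfu_table(p)
        assert len(back) == 4
        assert {s.condition for s in back} == {"warm", "cold"}
        assert np.array_equal(back[0].times_days, rows[0].times_days)
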