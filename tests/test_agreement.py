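"""Agreement statistics vs from-scratch ANOVA/moment/OLS oracles."""

import numpy as np
import pytest

from bodycomp.agreement import (PairedMeasurements, agreement_summary,
                                bland_altman, group_ttest, icc_2way_absolute,
                                pearson, trend_test)


def icc21_oracle(a, b):
    """Direct two-way ANOVA mean squares, written independently."""
    y = np.column_stack([a, b]).astype(float)
    n, k = y.shape
    grand = y.mean()
    ms_r = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand) ** 2).sum()
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


def _paired(a, b):
    return PairedMeasurements([f"s{i}" for i in range(len(a))], a, b)


TOY_A = np.array([9.0, 10.5, 12.0, 8.0, 14.5, 11.0])
TOY_B = np.array([9.4, 10.0, 12.8, 7.5, 13.9, 11.6])


class TestICC:
    def test_identical_raters_perfect(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_2way_absolute(_paired(a, a)) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_2way_absolute(_paired(a, a + 1.0)) < 1.0

    def test_toy_table_matches_anova_oracle(self):
        got = icc_2way_absolute(_paired(TOY_A, TOY_B))
        assert got == pytest.approx(icc21_oracle(TOY_A, TOY_B), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = len(TOY_A)
        df = pd.DataFrame({
            "subject": list(range(n)) * 2,
            "rater": ["a"] * n + ["b"] * n,
            "score": np.concatenate([TOY_A, TOY_B]),
        })
        icc = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        sel = icc["Type"].isin(["ICC2", "ICC(A,1)"])  # absolute, single measure
        ref = float(icc.loc[sel, "ICC"].iloc[0])
        assert icc_2way_absolute(_paired(TOY_A, TOY_B)) == pytest.approx(ref, abs=1e-9)

    def test_affine_invariance_and_bias_sensitivity(self, rng):
        a = rng.normal(50, 10, 30)
        b = a + rng.normal(0, 1, 30)
        base = icc_2way_absolute(_paired(a, b))
        rescaled = icc_2way_absolute(_paired(3 * a + 7, 3 * b + 7))
        assert rescaled == pytest.approx(base, abs=1e-10)
        biased = icc_2way_absolute(_paired(a, b + 5.0))
        assert biased < base

    def test_zero_between_subject_variance_undefined(self):
        a = np.full(5, 3.0)
        assert np.isnan(icc_2way_absolute(_paired(a, a)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_2way_absolute(_paired(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestBlandAltman:
    def test_identical_raters(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(_paired(a, a))
        assert ba["bias"] == 0.0 and ba["loa_low"] == 0.0 and ba["loa_high"] == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(_paired(a + 2.5, a))
        assert ba["bias"] == pytest.approx(2.5)
        assert ba["loa_low"] == pytest.approx(2.5)
        assert ba["loa_high"] == pytest.approx(2.5)

    def test_matches_moment_oracle(self, rng):
        a, b = rng.normal(10, 2, 40), rng.normal(10, 2, 40)
        ba = bland_altman(_paired(a, b))
        d = a - b
        assert ba["bias"] == pytest.approx(d.mean(), abs=1e-12)
        assert ba["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1),
                                               abs=1e-12)

    def test_loa_coverage_near_95pct(self):
        r = np.random.default_rng(7)
        a = r.normal(0, 1, 10_000)
        b = a + r.normal(0.5, 2.0, 10_000)
        ba = bland_altman(_paired(a, b))
        d = a - b
        inside = np.mean((d >= ba["loa_low"]) & (d <= ba["loa_high"]))
        # binomial tolerance around the Gaussian 95% interval
        assert abs(inside - 0.95) < 3 * np.sqrt(0.95 * 0.05 / 10_000) + 2e-3


class TestPearson:
    def test_affine_relations(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson(_paired(2 * a + 3, a)) == pytest.approx(1.0)
        assert pearson(_paired(-a, a)) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        want = (((a - a.mean()) * (b - b.mean())).sum()
                / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
        assert pearson(_paired(a, b)) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_missing(self):
        assert np.isnan(pearson(_paired(np.full(5, 1.0), np.arange(5.0))))


class TestTrend:
    def test_perfect_line(self):
        res = trend_test([1.0, 2.0, 3.0], [0, 1, 2])
        assert res["slope"] == pytest.approx(1.0)
        assert res["p_trend"] < 1e-8

    def test_slope_matches_closed_form(self, rng):
        g = rng.integers(0, 3, 30)
        v = 2.0 * g + rng.normal(0, 1, 30)
        res = trend_test(v, g)
        want = (((g - g.mean()) * (v - v.mean())).sum()
                / ((g - g.mean()) ** 2).sum())
        assert res["slope"] == pytest.approx(want, abs=1e-12)

    def test_p_consistent_with_permutation_null(self):
        r = np.random.default_rng(11)
        g = np.repeat([0, 1, 2], 10)
        v = 0.8 * g + r.normal(0, 1.2, 30)
        obs = trend_test(v, g)
        perm_slopes = []
        for _ in range(1000):
            perm_slopes.append(trend_test(v, r.permutation(g))["slope"])
        perm_slopes = np.asarray(perm_slopes)
        assert abs(perm_slopes.mean()) < 3 * perm_slopes.std() / np.sqrt(1000)
        p_perm = np.mean(np.abs(perm_slopes) >= abs(obs["slope"]))
        # parametric and permutation p agree within Monte-Carlo error
        assert abs(p_perm - obs["p_trend"]) < 0.05

    def test_single_grade_rejected(self):
        with pytest.raises(ValueError):
            trend_test([1.0, 2.0, 3.0], [1, 1, 1])


class TestTTest:
    def test_identical_groups(self):
        assert group_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == {"t": 0.0, "p": 1.0}

    def test_separated_groups(self):
        r = np.random.default_rng(0)
        res = group_ttest(r.normal(0, 0.1, 20), r.normal(10, 0.1, 20))
        assert res["p"] < 1e-6

    def test_welch_matches_textbook_formula(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 17)
        res = group_ttest(x, y, welch=True)
        se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        assert res["t"] == pytest.approx((x.mean() - y.mean()) / se, abs=1e-12)

    def test_pooled_matches_textbook_formula(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.2, 1, 14)
        res = group_ttest(x, y, welch=False)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        want = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert res["t"] == pytest.approx(want, abs=1e-12)


def test_agreement_summary_panel():
    res = agreement_summary(_paired(TOY_A, TOY_B))
    d = res.as_dict()
    assert set(d) == {"pearson_r", "icc", "bland_altman", "n"}
    assert d["n"] == 6
    assert d["bland_altman"]["loa_low"] <= d["bland_altman"]["bias"] \
        <= d["bland_altman"]["loa_high"]


def test_missing_pairs_rejected():
    with pytest.raises(ValueError):
        _paired(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))
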