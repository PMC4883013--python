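"""Cronbach's-alpha ICC, Feldt intervals, cross-version matrices, medians."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from subfieldstats.datatypes import (
    InsufficientDataError,
    MeasurementTable,
    UndefinedResultError,
)
from subfieldstats.refdata import (
    TRANS_PLATFORM_ICC_V53,
    TRANS_PLATFORM_ICC_V60,
)
from subfieldstats.reliability import (
    alpha_confidence_interval,
    cronbach_alpha,
    cross_version_icc_matrix,
    median_icc,
)
from subfieldstats.simulate import simulate_version_pair


def _table(values, region="r"):
    values = np.asarray(values, dtype=float)
    return MeasurementTable(
        region, [f"c{j}" for j in range(values.shape[1])], values,
        [f"s{i}" for i in range(values.shape[0])],
    )


def _loop_cov(x, y):
    """Independent unbiased covariance (explicit loops, no numpy.cov)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self, rng):
        col = rng.normal(100, 10, size=8)
        assert cronbach_alpha(_table(np.column_stack([col, col]))) == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 1.0, 1.0, 2.0])
        # orthogonalize b against a so the sample covariance is exactly 0
        b = b - _loop_cov(a, b) / _loop_cov(a, a) * a
        assert abs(_loop_cov(a, b)) < 1e-12
        assert cronbach_alpha(_table(np.column_stack([a, b]))) == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_arithmetic(self, rng):
        # 6 subjects, 2 raters: alpha must equal the formula evaluated on
        # independently (loop-)computed covariance-matrix entries
        x = rng.normal(0, 1, size=(6, 2)) + rng.normal(0, 1, size=(6, 1))
        v1 = _loop_cov(x[:, 0], x[:, 0])
        v2 = _loop_cov(x[:, 1], x[:, 1])
        c = _loop_cov(x[:, 0], x[:, 1])
        expected = 2 * c / ((v1 + v2) / 2 + c)
        assert cronbach_alpha(_table(x)) == pytest.approx(expected, rel=1e-12)

    def test_three_raters_matches_formula(self, rng):
        x = rng.normal(0, 1, size=(10, 3)) + rng.normal(0, 1, size=(10, 1))
        cov = [[_loop_cov(x[:, i], x[:, j]) for j in range(3)] for i in range(3)]
        vbar = np.mean([cov[i][i] for i in range(3)])
        cbar = np.mean([cov[i][j] for i in range(3) for j in range(3) if i != j])
        expected = 3 * cbar / (vbar + 2 * cbar)
        assert cronbach_alpha(_table(x)) == pytest.approx(expected, rel=1e-12)

    def test_constant_table_undefined(self):
        with pytest.raises(UndefinedResultError):
            cronbach_alpha(_table(np.full((5, 2), 7.0)))

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            cronbach_alpha(_table(np.array([[1.0, 2.0], [2.0, 3.0]])))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_shift_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(8, 3)) + rng.normal(0, 1, size=(8, 1))
        a0 = cronbach_alpha(_table(x))
        shifted = x + np.array([5.0, -3.0, 100.0])  # per-rater constants
        scaled = 3.7 * x                            # common rescaling
        assert cronbach_alpha(_table(shifted)) == pytest.approx(a0, rel=1e-9)
        assert cronbach_alpha(_table(scaled)) == pytest.approx(a0, rel=1e-9)
        assert a0 <= 1.0 + 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_two_rater_identity(self, seed):
        # alpha(2 raters) = 4c / (v1 + v2 + 2c)
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(7, 2)) + rng.normal(0, 1, size=(7, 1))
        v1 = _loop_cov(x[:, 0], x[:, 0])
        v2 = _loop_cov(x[:, 1], x[:, 1])
        c = _loop_cov(x[:, 0], x[:, 1])
        assert cronbach_alpha(_table(x)) == pytest.approx(
            4 * c / (v1 + v2 + 2 * c), rel=1e-9
        )


class TestFeldtInterval:
    def test_matches_textbook_formula(self):
        # independent recomputation of the Feldt bounds from F quantiles
        alpha, n, k, level = 0.9, 39, 2, 0.95
        lo, hi = alpha_confidence_interval(alpha, n, k, level)
        df1, df2 = n - 1, (n - 1) * (k - 1)
        exp_lo = 1 - (1 - alpha) * stats.f.ppf(0.975, df1, df2)
        exp_hi = 1 - (1 - alpha) * stats.f.ppf(0.025, df1, df2)
        assert lo == pytest.approx(exp_lo, rel=1e-12)
        assert hi == pytest.approx(exp_hi, rel=1e-12)
        assert lo < alpha < hi

    def test_null_alpha_interval_straddles_zero(self):
        lo, hi = alpha_confidence_interval(0.0, 20, 2)
        assert lo < 0.0 < hi

    def test_interval_widens_with_level(self):
        widths = []
        for level in (0.8, 0.9, 0.95, 0.99):
            lo, hi = alpha_confidence_interval(0.85, 30, 2, level)
            widths.append(hi - lo)
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_degenerate_at_one(self):
        assert alpha_confidence_interval(1.0, 30, 2) == (1.0, 1.0)


class TestCrossVersionMatrix:
    def _frames(self, rng, n=30):
        idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
        v6 = pd.DataFrame(
            {r: rng.normal(500, 60, size=n)
             for r in ["hippocampal_tail", "CA1", "CA3", "CA4", "fimbria",
                       "fissure", "presubiculum", "subiculum"]},
            index=idx,
        )
        return idx, v6

    def test_identical_tables_diagonal_one(self, rng):
        _, v6 = self._frames(rng)
        v53 = v6.rename(columns={"CA3": "CA2_3", "CA4": "CA4_DG"})
        out = cross_version_icc_matrix(v6, v53)
        assert out.loc["hippocampal_tail", "hippocampal_tail"] == pytest.approx(1.0)
        assert out.loc["subiculum", "subiculum"] == pytest.approx(1.0)
        # unpaired cells stay empty
        assert np.isnan(out.loc["hippocampal_tail", "CA1"])

    def test_constant_shift_keeps_consistency_icc_at_one(self, rng):
        _, v6 = self._frames(rng)
        v53 = (v6 + 250.0).rename(columns={"CA3": "CA2_3", "CA4": "CA4_DG"})
        out = cross_version_icc_matrix(v6, v53)
        assert out.loc["CA1", "CA1"] == pytest.approx(1.0)

    def test_cross_pairings_present(self, rng):
        _, v6 = self._frames(rng)
        v53 = v6.rename(columns={"CA3": "CA2_3", "CA4": "CA4_DG"})
        out = cross_version_icc_matrix(v6, v53)
        # the CA sectors are compared against all three v5.3 CA labels
        for row in ("CA1", "CA3", "CA4"):
            for col in ("CA1", "CA2_3", "CA4_DG"):
                assert np.isfinite(out.loc[row, col])

    def test_simulated_correlation_recovered(self, rng):
        n = 200
        base = pd.Series(rng.normal(500, 60, size=n),
                         index=[f"s{i}" for i in range(n)])
        tbl = simulate_version_pair(base, correlation=0.8, seed=7)
        v6 = pd.DataFrame({"subiculum": tbl.values[:, 0]}, index=base.index)
        v53 = pd.DataFrame({"subiculum": tbl.values[:, 1]}, index=base.index)
        out = cross_version_icc_matrix(v6, v53,
                                       pairing={"subiculum": ["subiculum"]})
        # independent brute-force covariance arithmetic on the same data
        x, y = tbl.values[:, 0], tbl.values[:, 1]
        c = np.cov(x, y, ddof=1)
        expected = 2 * c[0, 1] / ((c[0, 0] + c[1, 1]) / 2 + c[0, 1])
        assert out.loc["subiculum", "subiculum"] == pytest.approx(expected, rel=1e-12)
        assert out.loc["subiculum", "subiculum"] == pytest.approx(
            2 * 0.8 / 1.8, abs=0.07
        )

    def test_disjoint_subjects_error(self, rng):
        _, v6 = self._frames(rng)
        v53 = v6.rename(columns={"CA3": "CA2_3", "CA4": "CA4_DG"})
        v53.index = [f"t{i}" for i in range(len(v53))]
        with pytest.raises(InsufficientDataError):
            cross_version_icc_matrix(v6, v53)


class TestMedianICC:
    def test_published_transplatform_medians(self):
        assert median_icc(list(TRANS_PLATFORM_ICC_V53.values())) == pytest.approx(0.855)
        assert median_icc(list(TRANS_PLATFORM_ICC_V60.values())) == pytest.approx(0.853)

    def test_singleton_and_even_count(self):
        assert median_icc([0.7]) == 0.7
        assert median_icc([0.6, 0.8]) == pytest.approx(0.7)

    def test_empty_list_error(self):
        with pytest.raises(InsufficientDataError):
            median_icc([])
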