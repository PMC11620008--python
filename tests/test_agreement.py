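"""Dice, ICC(A,1) with CIs, reliability categories, profile smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import onhmetry as om
from onhmetry.agreement import (
    abs_diff_stats,
    anova_mean_squares,
    dice,
    difference_profile,
    icc_a1,
    icc_category,
    icc_consistency,
    smooth_profile,
)
from onhmetry.exceptions import UndefinedStatisticError


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_partial_overlap(self):
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a, b) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        assert dice(np.zeros(5, dtype=bool), np.zeros(5, dtype=bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) < 0.4
        b = rng.random((6, 6)) < 0.4
        assert dice(a, b) == dice(b, a)


def mcgraw_wong_oracle(x):
    """Independent transcription: statsmodels ANOVA mean squares plus the
    published absolute-agreement single-measure formulas."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = x.shape
    df = pd.DataFrame({
        "y": x.ravel(),
        "subject": np.repeat(np.arange(n), k).astype(str),
        "rater": np.tile(np.arange(k), n).astype(str),
    })
    model = ols("y ~ C(subject) + C(rater)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    msr = table.loc["C(subject)", "sum_sq"] / table.loc["C(subject)", "df"]
    msc = table.loc["C(rater)", "sum_sq"] / table.loc["C(rater)", "df"]
    mse = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_l = stats.f.ppf(0.975, n - 1, v)
    f_u = stats.f.ppf(0.975, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return icc, lo, hi


class TestIccA1:
    def test_perfect_agreement_is_one(self):
        x = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        rep = icc_a1(x)
        assert rep.icc_estimate == pytest.approx(1.0)
        assert rep.category == "excellent"

    def test_rater_offset_strictly_decreases_absolute_agreement(self):
        rng = np.random.default_rng(0)
        x = np.tile(rng.normal(100, 10, (8, 1)), (1, 3))
        x += rng.normal(0, 1, x.shape)
        base = icc_a1(x).icc_estimate
        shifted = x.copy()
        shifted[:, 2] += 15.0
        assert icc_a1(shifted).icc_estimate < base

    def test_matches_independent_anova_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = (rng.normal(100, 10, (8, 1))
                 + rng.normal(0, 4, (1, 3)) + rng.normal(0, 5, (8, 3)))
            rep = icc_a1(x)
            icc, lo, hi = mcgraw_wong_oracle(x)
            assert rep.icc_estimate == pytest.approx(icc, abs=1e-10)
            assert rep.ci_low == pytest.approx(lo, abs=1e-10)
            assert rep.ci_high == pytest.approx(hi, abs=1e-10)

    def test_matches_pingouin_estimate(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        x = rng.normal(100, 10, (8, 3))
        df = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
        })
        row = pg.intraclass_corr(df, "subject", "rater",
                                 "y").set_index("Type").loc["ICC(A,1)"]
        rep = icc_a1(x)
        assert rep.icc_estimate == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert rep.ci_low == pytest.approx(row["CI95"][0], abs=0.006)
        assert rep.ci_high == pytest.approx(row["CI95"][1], abs=0.006)

    def test_negative_ci_bounds_not_clipped(self):
        rng = np.random.default_rng(11)
        # little subject variance: lower bound goes negative
        x = rng.normal(0, 1, (6, 3))
        rep = icc_a1(x)
        assert rep.ci_low < 0

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_a1(np.full((5, 3), 7.0))

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 8, (8, 3))
        rep1 = icc_a1(x)
        rep2 = icc_a1(x[rng.permutation(8)])
        assert rep1.icc_estimate == pytest.approx(rep2.icc_estimate,
                                                  abs=1e-12)
        assert rep1.ci_low == pytest.approx(rep2.ci_low, abs=1e-12)

    def test_absolute_agreement_below_consistency_under_rater_bias(self):
        # systematic rater offsets penalise absolute agreement but not
        # consistency
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = (rng.normal(100, 10, (10, 1))
                 + np.array([[0.0, 6.0, -3.0]]) + rng.normal(0, 2, (10, 3)))
            assert icc_a1(x).icc_estimate < icc_consistency(x)


class TestIccCategory:
    @pytest.mark.parametrize("value,label", [
        (0.983, "excellent"),
        (0.667, "moderate"),
        (0.49, "poor"),
        (0.5, "moderate"),
        (0.75, "good"),
        (0.9, "good"),
        (0.901, "excellent"),
        (-0.2, "poor"),
    ])
    def test_thresholds(self, value, label):
        assert icc_category(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            icc_category(1.2)


class TestAbsDiffStats:
    def test_identical_vectors(self):
        assert abs_diff_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0)

    def test_symmetric_differences(self):
        mean, sd = abs_diff_stats([5.0, 0.0], [0.0, 5.0])
        assert mean == 5.0 and sd == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        mean, sd = abs_diff_stats(x, y)
        d = np.abs(x - y)
        assert mean == pytest.approx(d.mean())
        assert sd == pytest.approx(d.std(ddof=1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            abs_diff_stats([1.0, 2.0], [1.0])


def uniform_profile(values):
    values = np.asarray(values, dtype=float)
    n = values.size
    return om.AngularProfile(np.arange(n) * (360.0 / n), values)


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        p = uniform_profile(np.full(360, 80.0))
        assert np.allclose(smooth_profile(p, 9.0).values, 80.0)

    def test_impulse_response_is_box_filter(self):
        vals = np.zeros(360)
        vals[0] = 1.0
        sm = smooth_profile(uniform_profile(vals), 9.0)
        expected = np.zeros(360)
        expected[np.r_[0:5, 356:360]] = 1.0 / 9.0  # [-4 deg, +4 deg]
        assert np.allclose(sm.values, expected)

    def test_circular_mean_preserved_exactly(self):
        rng = np.random.default_rng(8)
        p = uniform_profile(rng.normal(100, 20, 720))
        sm = smooth_profile(p, 9.0)
        assert sm.values.mean() == pytest.approx(p.values.mean(), abs=1e-9)

    def test_commutes_with_rotation(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, 360)
        sm_then_rot = np.roll(smooth_profile(uniform_profile(vals),
                                             9.0).values, 20)
        rot_then_sm = smooth_profile(uniform_profile(np.roll(vals, 20)),
                                     9.0).values
        assert np.allclose(sm_then_rot, rot_then_sm)

    def test_window_over_360_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(uniform_profile(np.zeros(36)), 400.0)


class TestDifferenceProfile:
    def test_identical_profiles_give_zero(self):
        p = uniform_profile(np.arange(36.0))
        d, mean = difference_profile(p, p)
        assert np.allclose(d.values, 0.0) and mean == 0.0

    def test_constant_offset(self):
        a = uniform_profile(np.full(36, 100.0))
        b = uniform_profile(np.full(36, 110.0))
        d, mean = difference_profile(a, b)
        assert np.allclose(d.values, -10.0) and mean == -10.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = uniform_profile(rng.normal(size=72))
        b = uniform_profile(rng.normal(size=72))
        d_ab, _ = difference_profile(a, b)
        d_ba, _ = difference_profile(b, a)
        assert np.allclose(d_ab.values, -d_ba.values)

    def test_incompatible_grids_rejected(self):
        with pytest.raises(ValueError):
            difference_profile(uniform_profile(np.zeros(36)),
                               uniform_profile(np.zeros(40)))


class TestMeanSquares:
    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 4))
        msr, msc, mse = anova_mean_squares(x)
        total = ((x - x.mean()) ** 2).sum()
        assert (msr * 6 + msc * 3 + mse * 18) == pytest.approx(total)
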