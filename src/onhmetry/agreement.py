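"""Agreement statistics for cross-device biomarker comparison.

Implements the Dice similarity coefficient for segmentation overlap, the
two-way mixed-model, absolute-agreement, single-measure intraclass
correlation coefficient ICC(A,1) with its F-based 95% confidence
interval, the conventional reliability categories (poor < 0.5, moderate
[0.5, 0.75), good [0.75, 0.9], excellent > 0.9), absolute-difference
summaries, and circular profile smoothing/differencing.

ICC(A,1) follows the McGraw & Wong parameterisation. With ``n`` subjects
and ``k`` raters and the two-way ANOVA mean squares MSR (rows/subjects),
MSC (columns/raters) and MSE (residual):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

The confidence bounds use the F-based absolute-agreement interval with
Satterthwaite degrees of freedom; negative lower bounds are legitimate
and are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedStatisticError
from .geometry import AngularProfile


@dataclass
class AgreementReport:
    icc_estimate: float
    ci_low: float
    ci_high: float
    category: str
    n_subjects: int
    n_raters: int
    confidence: float = 0.95

    def __post_init__(self):
        if not (self.ci_low <= self.icc_estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def dice(mask_a, mask_b) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Two empty masks are in perfect agreement on absence: DSC = 1.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def multilabel_dice(seg_a, seg_b, scheme) -> dict:
    """Per-structure DSC between two label arrays of equal shape."""
    a = np.asarray(seg_a)
    b = np.asarray(seg_b)
    if a.shape != b.shape:
        raise ValueError("segmentation shapes differ")
    return {name: dice(a == code, b == code)
            for name, code in scheme.to_dict().items()}


def anova_mean_squares(table):
    """Two-way ANOVA mean squares (MSR, MSC, MSE) of a subjects x raters table."""
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x raters)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_a1(table, confidence: float = 0.95) -> AgreementReport:
    """ICC(A,1): two-way mixed model, absolute agreement, single measure.

    ``table`` is an (n_subjects x k_raters) array with no missing cells,
    n >= 3 and k >= 2. Returns the estimate, the F-based two-sided CI and
    the reliability category.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("table has missing cells")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    msr, msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("degenerate variance decomposition")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    # Satterthwaite df for the absolute-agreement interval
    a = (k * icc) / (n * (1.0 - icc)) if icc != 1.0 else np.inf
    if np.isinf(a):
        lo = hi = 1.0
    else:
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo = (n * (msr - f_l * mse)
              / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_u * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo = min(lo, icc)
    hi = max(hi, icc)
    return AgreementReport(
        icc_estimate=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        category=icc_category(float(icc)),
        n_subjects=n,
        n_raters=k,
        confidence=confidence,
    )


def icc_consistency(table) -> float:
    """ICC(C,1), the consistency counterpart (rater bias not penalised)."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    msr, _msc, mse = anova_mean_squares(x)
    return float((msr - mse) / (msr + (k - 1) * mse))


def icc_category(value: float) -> str:
    """Reliability category for an ICC value.

    poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent. The 0.9
    boundary belongs to "good" ("greater than 0.90" is excellent).
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def abs_diff_stats(x, y):
    """Mean and sample SD (n-1) of the absolute differences |x - y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = np.abs(x - y)
    return float(d.mean()), float(d.std(ddof=1))


def smooth_profile(profile: AngularProfile, window_deg: float = 9.0) -> AngularProfile:
    """Circular (wrap-around) centred moving average of an angular profile.

    Requires an equally spaced profile. The box window covers all samples
    within ``window_deg / 2`` of the centre sample; a 9° window on a 1°
    grid averages 9 samples. The circular mean is preserved exactly.
    """
    if window_deg >= 360.0:
        raise ValueError("smoothing window must be < 360 degrees")
    if not profile.is_uniform():
        raise ValueError("smoothing requires an equally spaced profile")
    n = len(profile)
    step = 360.0 / n
    m = int(np.floor(window_deg / 2.0 / step + 1e-9))
    size = 2 * m + 1
    from scipy.ndimage import uniform_filter1d

    vals = uniform_filter1d(profile.values, size=size, mode="wrap")
    und = uniform_filter1d(profile.undefined.astype(float), size=size,
                           mode="wrap") > 1e-12
    return AngularProfile(angles_deg=profile.angles_deg.copy(), values=vals,
                          undefined=und, convention=profile.convention)


def difference_profile(profile_a: AngularProfile, profile_b: AngularProfile):
    """Pointwise A - B profile plus the scalar overall mean difference.

    The profiles must share the same angular grid. Returns
    ``(AngularProfile, mean_difference)``; samples undefined in either
    input are undefined in the difference and excluded from the mean.
    """
    if (len(profile_a) != len(profile_b)
            or not np.allclose(profile_a.angles_deg, profile_b.angles_deg)):
        raise ValueError("profiles are on incompatible angular grids")
    diff = profile_a.values - profile_b.values
    und = profile_a.undefined | profile_b.undefined
    prof = AngularProfile(angles_deg=profile_a.angles_deg.copy(), values=diff,
                          undefined=und)
    return prof, prof.mean()
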