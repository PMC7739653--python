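"""Cohort statistics: sex comparisons, effect sizes, correlations and
blockwise regression with incremental-R² variance partitioning.

Standard tests are delegated to scipy/statsmodels; this module owns the
composites specific to the analysis — the effect-size magnitude bands, the
summary-level Cohen's d, and the blockwise ΔR² bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .types import InputError


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError("group summary needs n >= 2")
        if self.sd < 0:
            raise InputError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        return cls(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


#: Magnitude bands for standardized mean differences: lower edge -> label.
#: Each boundary belongs to the higher band except 2.0, which is still
#: "large" because "very large" is strictly > 2.0.
_ES_BANDS = ((2.0, "very large"), (1.2, "large"), (0.6, "moderate"), (0.2, "small"))


def classify_effect_size(d: float) -> str:
    """Magnitude label of a Cohen's d value."""
    if not np.isfinite(d):
        raise InputError("effect size must be finite")
    ad = abs(d)
    for lower, label in _ES_BANDS:
        met = ad > lower if lower == 2.0 else ad >= lower
        if met:
            return label
    return "trivial"


@dataclass(frozen=True)
class EffectSize:
    d: float
    magnitude: str

    def __post_init__(self) -> None:
        if self.magnitude != classify_effect_size(self.d):
            raise InputError("magnitude inconsistent with |d| under the band map")


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> EffectSize:
    """Cohen's d between two group summaries.

    Uses the root-mean-square of the two SDs as the pooling denominator;
    with equal group sizes this equals the df-weighted pooled SD. The sign
    is dropped: the magnitude of the difference is what the bands grade.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise InputError("effect size undefined: both group SDs are zero")
    pooled = np.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    d = float(abs(g2.mean - g1.mean) / pooled)
    return EffectSize(d=d, magnitude=classify_effect_size(d))


def students_t_test(
    g1: Sequence[float], g2: Sequence[float], *, welch: bool = False
) -> tuple[float, int, float]:
    """Two-tailed independent-samples t-test.

    Pooled-variance Student's t by default (df = n1+n2−2); set ``welch=True``
    for the unequal-variance variant. Zero pooled variance with equal means
    returns (0, df, 1.0) by convention; with unequal means the statistic is
    undefined and an error is raised.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("both groups need n >= 2")
    df = int(a.size + b.size - 2)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise InputError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = int(np.floor(res.df))
    return float(res.statistic), df, float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p (t-transform, n−2 df)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size:
        raise InputError("x and y must have equal length")
    if a.size < 3:
        raise InputError("need n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise InputError("zero variance input")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality statistic; a gate-report, not a gate."""
    a = np.asarray(x, dtype=float)
    if not 3 <= a.size <= 5000:
        raise InputError("Shapiro-Wilk requires 3 <= n <= 5000")
    if a.std() == 0:
        raise InputError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(a)
    return float(w), float(p)


@dataclass(frozen=True)
class RegressionPartition:
    """Blockwise OLS variance partition.

    ``delta_r2[k]`` is the R² gained when predictor k enters the model after
    predictors 0..k−1; increments sum to the full-model R². ``p_value`` is
    the full-model F-test p.
    """

    predictors: tuple[str, ...]
    delta_r2: tuple[float, ...]
    total_r2: float
    p_value: float

    def __post_init__(self) -> None:
        if abs(sum(self.delta_r2) - self.total_r2) > 1e-9:
            raise InputError("incremental R² do not sum to total R²")
        if not 0.0 <= self.total_r2 <= 1.0 + 1e-12:
            raise InputError("total R² out of [0, 1]")


def blockwise_regression(
    y: Sequence[float],
    X: Sequence[Sequence[float]] | np.ndarray,
    predictor_names: Sequence[str] | None = None,
) -> RegressionPartition:
    """Sequential-entry OLS: one predictor per block, in caller order.

    Fits the nested models y ~ x1, y ~ x1+x2, ... with intercepts and
    reports each predictor's increment in R². The overall p comes from the
    full model's F test.
    """
    yv = np.asarray(y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n, p = Xm.shape
    if yv.size != n:
        raise InputError("y and X row counts differ")
    if n <= p + 1:
        raise InputError(f"need n > p+1 observations, got n={n}, p={p}")
    names = (
        tuple(predictor_names)
        if predictor_names is not None
        else tuple(f"x{i + 1}" for i in range(p))
    )
    if len(names) != p:
        raise InputError("predictor_names length mismatch")

    r2 = [0.0]
    full_res = None
    for k in range(1, p + 1):
        design = sm.add_constant(Xm[:, :k])
        if np.linalg.matrix_rank(design, tol=1e-10 * max(n, k)) < k + 1:
            raise InputError(f"singular fit: predictor {names[k - 1]!r} is collinear")
        res = sm.OLS(yv, design).fit()
        r2.append(float(res.rsquared))
        full_res = res
    assert full_res is not None
    deltas = tuple(r2[k] - r2[k - 1] for k in range(1, p + 1))
    # nested OLS R² is non-decreasing; clip float dust so invariants hold
    deltas = tuple(max(d, 0.0) for d in deltas)
    total = float(sum(deltas))
    return RegressionPartition(
        predictors=names,
        delta_r2=deltas,
        total_r2=total,
        p_value=float(full_res.f_pvalue),
    )
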