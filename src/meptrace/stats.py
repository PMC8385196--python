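"""Two-group comparison flow and summary statistics.

Group comparisons follow the gated flow standard in this literature: each
group is checked for normality (Shapiro–Wilk); if either group is
non-normal the two-sided Mann–Whitney U-test is used; otherwise variance
homogeneity is checked (Levene, mean-centred as in SPSS) and either the
pooled-variance t-test or the separate-variance (Welch) t-test is applied.
Summaries are reported as mean ± SEM, and headline effects as percent
improvement over a reference, rounded half away from zero to 2 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

POOLED_T = "pooled_t"
WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupSample:
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a group needs at least 2 finite values")
        if not np.all(np.isfinite(v)):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TestResult:
    branch: str
    statistic: float
    p_value: float
    normality_p: tuple[float, float]  # Shapiro–Wilk p per group (NaN if undefined)
    levene_p: float | None  # None when the Levene gate was not reached
    alpha: float


def mean_sem(sample) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (SD with n−1 over √n)."""
    v = np.asarray(sample.values if isinstance(sample, GroupSample) else sample,
                   dtype=float)
    if v.size < 2:
        raise ValueError("mean ± SEM needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact enumeration for small groups (no ties); tie-corrected normal
    # approximation otherwise
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) < 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(x: GroupSample, y: GroupSample,
                   alpha: float = 0.05) -> TestResult:
    """Compare two groups with the normality/variance-gated test flow.

    Branching (two-sided throughout): Mann–Whitney U if either group fails
    Shapiro–Wilk at ``alpha`` (or has zero variance, where Shapiro–Wilk is
    undefined); else Welch t if Levene fails at ``alpha``; else pooled t.
    """
    if x.n < 3 or y.n < 3:
        raise ValueError("each group needs n >= 3 for the normality gate")

    sw_p = []
    degenerate = False
    for g in (x, y):
        if np.ptp(g.values) == 0:
            degenerate = True
            sw_p.append(float("nan"))
        else:
            sw_p.append(float(sps.shapiro(g.values).pvalue))
    normality_p = (sw_p[0], sw_p[1])

    if degenerate:
        warnings.warn("zero-variance group: Shapiro–Wilk undefined, routing "
                      "to Mann–Whitney", stacklevel=2)
    nonnormal = degenerate or any(
        (not np.isnan(p)) and p < alpha for p in sw_p)

    if nonnormal:
        stat, p = _mann_whitney(x.values, y.values)
        return TestResult(MANN_WHITNEY, stat, p, normality_p, None, alpha)

    levene_p = float(sps.levene(x.values, y.values, center="mean").pvalue)
    equal_var = levene_p >= alpha
    res = sps.ttest_ind(x.values, y.values, equal_var=equal_var)
    branch = POOLED_T if equal_var else WELCH_T
    return TestResult(branch, float(res.statistic), float(res.pvalue),
                      normality_p, levene_p, alpha)


def null_rejection_rate(n_reps: int = 2000, n_per_group: int = 8,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the full gated procedure under the null.

    Simulates ``n_reps`` pairs of equal-mean normal samples and applies
    :func:`compare_groups` to each; returns the fraction of rejections at
    ``alpha``.  For a well-calibrated adaptive flow this should sit close
    to ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = GroupSample(rng.normal(0.0, 1.0, n_per_group))
        y = GroupSample(rng.normal(0.0, 1.0, n_per_group))
        if compare_groups(x, y, alpha=alpha).p_value < alpha:
            rejections += 1
    return rejections / n_reps


def percent_improvement(value_new: float, value_ref: float) -> float:
    """Percent change of ``value_new`` relative to ``value_ref``.

    ``100 × (new − ref) / ref``, rounded half away from zero to 2 decimals
    (the convention used for reported improvement percentages).
    """
    if value_ref <= 0:
        raise ValueError("reference value must be positive")
    pct = Decimal(100) \
        * (Decimal(repr(float(value_new))) - Decimal(repr(float(value_ref)))) \
        / Decimal(repr(float(value_ref)))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
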