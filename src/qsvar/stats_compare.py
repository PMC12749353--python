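"""Group-comparison statistics with a study-wide FDR pass.

All tests are two-sided.  Raw p-values from every comparison in a study are
collected and corrected jointly with the Benjamini–Hochberg step-up
procedure at the end of the run, so the adjusted values control the false
discovery rate across the whole battery, not per figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

EXACT_MAX_N = 8  # exact rank-sum null up to this smaller-sample size, ties absent


@dataclass
class StatResult:
    """One two-sided test: statistic, raw p, effect summary and group sizes.

    ``p_adjusted`` is filled by the study-wide BH pass (:class:`StudyResults`).
    """

    test_id: str
    statistic: float
    p_raw: float
    effect: float
    n1: int
    n2: int
    figure_tag: str = ""
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


def wilcoxon_rank_sum(x, y, test_id: str = "wilcoxon", figure_tag: str = "") -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and the pooled data are tie-free; otherwise the normal
    approximation with continuity and tie corrections.  The effect summary
    is the difference of medians (x − y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return StatResult(test_id, float(res.statistic), float(res.pvalue),
                      float(np.median(x) - np.median(y)), x.size, y.size,
                      figure_tag, extra={"method": method})


def prop_test_ci(k1: int, n1: int, k2: int, n2: int,
                 test_id: str = "prop", figure_tag: str = "") -> StatResult:
    """Two-proportion chi-square test (continuity-corrected) with Wilson CIs.

    The effect summary is the difference of sample proportions; per-group
    95% Wilson score intervals are returned in ``extra``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if k1 / n1 == k2 / n2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    ci1 = proportion_confint(k1, n1, alpha=0.05, method="wilson")
    ci2 = proportion_confint(k2, n2, alpha=0.05, method="wilson")
    return StatResult(test_id, float(chi2), float(p), k1 / n1 - k2 / n2, n1, n2,
                      figure_tag,
                      extra={"ci1": (float(ci1[0]), float(ci1[1])),
                             "ci2": (float(ci2[0]), float(ci2[1]))})


def ancova_group_effect(y, group, covariate,
                        test_id: str = "ancova", figure_tag: str = "") -> StatResult:
    """Group effect from OLS of y on a binary group plus one covariate.

    No interaction term; the reported statistic and two-sided p are the
    t-test of the group coefficient, and the effect summary is the adjusted
    group difference (the coefficient itself).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (len(y) == len(g) == len(z)):
        raise ValueError("inputs must have equal length")
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError("group must be binary")
    if min((g == v).sum() for v in groups) < 3:
        raise ValueError("need at least 3 observations per group")
    gi = (g == groups[1]).astype(float)
    X = sm.add_constant(np.column_stack([gi, z]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate is collinear with the group indicator")
    fit = sm.OLS(y, X).fit()
    coef, p, t = fit.params[1], fit.pvalues[1], fit.tvalues[1]
    return StatResult(test_id, float(t), float(p), float(coef),
                      int((gi == 0).sum()), int((gi == 1).sum()), figure_tag,
                      extra={"slope_covariate": float(fit.params[2]),
                             "resid_skew": float(stats.skew(fit.resid)),
                             "resid_normality_p": float(
                                 stats.shapiro(fit.resid).pvalue
                                 if 3 <= len(fit.resid) <= 5000 else math.nan)})


def spearman_partial(x, y, z, test_id: str = "spearman_partial",
                     figure_tag: str = "") -> StatResult:
    """Spearman partial correlation of x and y controlling for z.

    All three variables are rank-transformed (midranks for ties); the
    first-order partial correlation on the ranks is tested with the
    t-approximation on n − 3 degrees of freedom.  Returns NaN effect and
    p when any rank vector is constant (undefined).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValueError("need equal-length samples with n >= 4")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    if any(np.ptp(r) == 0 for r in (rx, ry, rz)):
        return StatResult(test_id, math.nan, math.nan, math.nan, n, 0, figure_tag)
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = math.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        return StatResult(test_id, math.nan, math.nan, math.nan, n, 0, figure_tag)
    rho = (rxy - rxz * ryz) / denom
    rho = max(-1.0, min(1.0, rho))
    df = n - 3
    if abs(rho) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = rho * math.sqrt(df / (1 - rho**2))
        p = 2 * stats.t.sf(abs(t), df)
    return StatResult(test_id, float(t), float(p), float(rho), n, 0, figure_tag)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class StudyResults:
    """Collects every test of a study run and applies one global BH pass."""

    def __init__(self) -> None:
        self.results: list[StatResult] = []

    def add(self, result: StatResult) -> StatResult:
        self.results.append(result)
        return result

    def finalize(self) -> list[StatResult]:
        """Adjust all collected p-values jointly (NaN p-values pass through)."""
        idx = [i for i, r in enumerate(self.results) if not math.isnan(r.p_raw)]
        if idx:
            adj = bh_correct([self.results[i].p_raw for i in idx])
            for i, a in zip(idx, adj):
                self.results[i].p_adjusted = float(a)
        return self.results

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"test_id": r.test_id, "figure_tag": r.figure_tag,
             "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adjusted,
             "n1": r.n1, "n2": r.n2, "effect": r.effect}
            for r in self.results
        ]
        return pd.DataFrame(
            rows, columns=["test_id", "figure_tag", "statistic", "p_raw",
                           "p_adj", "n1", "n2", "effect"])
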