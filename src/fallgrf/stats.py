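"""Nonparametric group comparison and correlation of entropy features.

Fallers and non-fallers are compared feature by feature with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test: the exact null distribution when both
groups have at most 10 tie-free observations, the tie-corrected normal
approximation otherwise. Association between features uses Spearman rank
correlation (mid-ranks for ties, two-sided t-approximation p-values).

Correlation magnitudes are bucketed with half-open intervals so every |r| has
exactly one category: high for |r| >= 0.50, moderate for [0.30, 0.50), weak
for [0.10, 0.30), negligible below 0.10. Group differences are flagged at
alpha = 0.1 by default; no multiple-testing correction is applied unless
requested, matching the exploratory character of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import FEATURE_NAMES, GROUP_ORDER
from .exceptions import ParameterError

CATEGORY_HIGH = "high"
CATEGORY_MODERATE = "moderate"
CATEGORY_WEAK = "weak"
CATEGORY_NEGLIGIBLE = "negligible"

#: Largest group size for which the exact rank-sum null is used (tie-free data).
EXACT_MAX_N = 10

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class GroupComparison:
    """Per-feature faller/non-faller summary and rank-sum test result."""

    feature: str
    faller_mean: float
    faller_sd: float
    nonfaller_mean: float
    nonfaller_sd: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationEntry:
    """Spearman correlation between two features with its magnitude category."""

    feature_a: str
    feature_b: str
    r: float
    p_value: float
    category: str


def rank_sum_compare(values_a, values_b) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Two-sided rank-sum p-value plus (mean, SD) of each group.

    Group SDs are sample SDs (ddof=1), as reported in cohort tables. Uses the
    exact null when both groups have <= 10 observations and the pooled data is
    tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0.0:
        p = float("nan")  # all observations identical: the test is degenerate
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    stat_a = (float(a.mean()), float(a.std(ddof=1)))
    stat_b = (float(b.mean()), float(b.std(ddof=1)))
    return p, stat_a, stat_b


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal lengths")
    if x.size < 3:
        raise ParameterError("need at least 3 paired values")
    import warnings

    with warnings.catch_warnings():
        # a constant input yields NaN by design; the caller flags it
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def categorize_correlation(r: float) -> str:
    """Magnitude bucket of a correlation coefficient.

    high: |r| >= 0.50; moderate: 0.30 <= |r| < 0.50; weak: 0.10 <= |r| < 0.30;
    negligible otherwise.
    """
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ParameterError("correlation coefficient must satisfy |r| <= 1")
    mag = abs(r)
    if mag >= 0.50:
        return CATEGORY_HIGH
    if mag >= 0.30:
        return CATEGORY_MODERATE
    if mag >= 0.10:
        return CATEGORY_WEAK
    return CATEGORY_NEGLIGIBLE


def adjust_p_values(p_values, method: str) -> np.ndarray:
    """Optional multiple-testing adjustment: 'bonferroni' or 'bh'."""
    p = np.asarray(p_values, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return sps.false_discovery_control(p, method="bh")
    raise ParameterError(f"unknown correction method {method!r}")


def compare_groups(
    features: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    groups: tuple[str, str] = GROUP_ORDER,
    correction: str | None = None,
) -> pd.DataFrame:
    """Faller vs non-faller rank-sum comparison, one row per feature.

    ``features`` is the feature table (``group`` column plus the eight entropy
    columns). Degenerate features (a constant column, or any all-tied pooled
    sample) are flagged rather than raising.
    """
    pos, neg = groups
    feature_cols = [c for c in FEATURE_NAMES if c in features.columns]
    if not feature_cols:
        raise ParameterError("feature table has no known entropy columns")
    a_mask = features["group"] == pos
    b_mask = features["group"] == neg
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ParameterError("each group needs at least 2 subjects")
    rows = []
    for name in feature_cols:
        a = features.loc[a_mask, name].to_numpy(dtype=float)
        b = features.loc[b_mask, name].to_numpy(dtype=float)
        p, (ma, sa), (mb, sb) = rank_sum_compare(a, b)
        rows.append({
            "feature": name,
            "faller_mean": ma, "faller_sd": sa,
            "nonfaller_mean": mb, "nonfaller_sd": sb,
            "p_value": p,
        })
    table = pd.DataFrame(rows)
    p_use = table["p_value"].to_numpy()
    if correction is not None:
        p_use = adjust_p_values(p_use, correction)
        table["p_adjusted"] = p_use
    table["degenerate"] = ~np.isfinite(table["p_value"].to_numpy())
    with np.errstate(invalid="ignore"):
        table["significant"] = np.where(np.isfinite(p_use), p_use < alpha, False)
    return table


def correlation_report(
    features: pd.DataFrame, selected: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman matrices (r, p, category) over selected features.

    The r matrix is symmetric with unit diagonal; the diagonal of the p matrix
    is NaN (self-correlation is not a test).
    """
    if selected is None:
        selected = [c for c in FEATURE_NAMES if c in features.columns]
    unknown = [c for c in selected if c not in features.columns]
    if unknown:
        raise ParameterError(f"unknown feature columns: {unknown}")
    m = len(selected)
    r_mat = np.eye(m)
    p_mat = np.full((m, m), np.nan)
    cat = np.empty((m, m), dtype=object)
    for i in range(m):
        cat[i, i] = CATEGORY_HIGH
        for j in range(i + 1, m):
            r, p = spearman_corr(
                features[selected[i]].to_numpy(dtype=float),
                features[selected[j]].to_numpy(dtype=float),
            )
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
            cat[i, j] = cat[j, i] = (
                categorize_correlation(r) if np.isfinite(r) else "undefined"
            )
    r_df = pd.DataFrame(r_mat, index=selected, columns=selected)
    p_df = pd.DataFrame(p_mat, index=selected, columns=selected)
    cat_df = pd.DataFrame(cat, index=selected, columns=selected)
    return r_df, p_df, cat_df


@dataclass
class ComparisonReport:
    """Bundle of the group-comparison table and correlation matrices."""

    group_comparison: pd.DataFrame
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    correlation_category: pd.DataFrame


def comparison_report(
    features: pd.DataFrame,
    selected: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    groups: tuple[str, str] = GROUP_ORDER,
    correction: str | None = None,
) -> ComparisonReport:
    """Group comparison over all features plus correlations over ``selected``."""
    comparison = compare_groups(features, alpha=alpha, groups=groups,
                                correction=correction)
    r_df, p_df, cat_df = correlation_report(features, selected)
    return ComparisonReport(comparison, r_df, p_df, cat_df)
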