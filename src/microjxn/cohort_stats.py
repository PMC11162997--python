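"""Cohort-level analytics on isoform-proportion tables.

All functions consume the cohort table produced by
:func:`microjxn.junction_quant.aggregate_cohort`: one row per sample, one
column per isoform proportion, plus metadata columns.  Samples with missing
proportions (zero anchor-donor reads) are excluded listwise per isoform.

Statistical choices: group comparisons use the Welch unequal-variance t-test
(two-sided); subtype specificity uses one-way ANOVA on raw proportions with
the adjusted R-squared ``1 - (1 - R^2)(n - 1)/(n - g)`` as the effect-size
summary and a significance flag at p < 0.001; time courses use the Spearman
rank correlation.  No multiple-testing correction is applied to flags, but a
Benjamini-Hochberg column is emitted alongside multi-isoform comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WelchResult",
    "GroupComparison",
    "SubtypeTest",
    "TrendResult",
    "tissue_ranking",
    "welch_ttest",
    "subtype_anova",
    "group_delta",
    "compare_groups",
    "trend_test",
]

logger = logging.getLogger(__name__)

#: ANOVA significance threshold for subtype specificity.
SUBTYPE_P_THRESHOLD = 1e-3


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.t)


@dataclass(frozen=True)
class GroupComparison:
    label: str
    mean_a: float
    mean_b: float
    delta: float  # mean_a - mean_b
    n_a: int
    n_b: int
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class SubtypeTest:
    label: str
    f_statistic: float
    p: float
    adjusted_r2: float
    n_groups: int
    n_samples: int
    significant: bool


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def _defined(cohort: pd.DataFrame, label: str) -> pd.DataFrame:
    sub = cohort[np.isfinite(cohort[label].astype(float))]
    if "excluded" in cohort.columns:
        sub = sub[~sub["excluded"].astype(bool)]
    return sub


def tissue_ranking(
    cohort: pd.DataFrame, label: str, k: int = 10, tissue_column: str = "tissue"
) -> pd.DataFrame:
    """Top-k tissues by mean proportion of one isoform.

    Means are arithmetic means over samples with defined proportions; ties
    are broken by tissue name so the ranking is stable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = _defined(cohort, label)
    if sub.empty:
        raise ValueError(f"no samples with defined {label!r} proportions")
    grouped = sub.groupby(tissue_column)[label].agg(["mean", "size"])
    grouped = grouped.rename(columns={"mean": "mean_proportion", "size": "n_samples"})
    grouped = grouped.reset_index().rename(columns={tissue_column: "tissue"})
    grouped = grouped.sort_values(
        ["mean_proportion", "tissue"], ascending=[False, True], kind="mergesort"
    )
    return grouped.head(k).reset_index(drop=True)


def welch_ttest(x, y) -> WelchResult:
    """Welch unequal-variance two-sample t-test (two-sided).

    Returns NaNs when either group has fewer than two defined values or both
    groups are constant (no usable variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
        return WelchResult(np.nan, np.nan, np.nan)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def subtype_anova(
    cohort: pd.DataFrame, label: str, subtype_column: str = "subtype"
) -> SubtypeTest:
    """One-way ANOVA of an isoform proportion across subtypes.

    Subtypes with fewer than two defined samples are dropped with a warning;
    at least two usable subtypes are required.  Adjusted R-squared is
    computed from the between/total sums of squares.
    """
    sub = _defined(cohort, label)
    groups = []
    for name, g in sub.groupby(subtype_column):
        vals = g[label].to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("subtype %r has %d sample(s); excluded from ANOVA", name, len(vals))
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("fewer than two subtypes with >= 2 samples")

    f_stat, p = stats.f_oneway(*groups)
    all_vals = np.concatenate(groups)
    n, g = len(all_vals), len(groups)
    grand = all_vals.mean()
    ss_total = float(np.sum((all_vals - grand) ** 2))
    ss_between = float(sum(len(v) * (v.mean() - grand) ** 2 for v in groups))
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - g)
    return SubtypeTest(
        label=label,
        f_statistic=float(f_stat),
        p=float(p),
        adjusted_r2=float(adj_r2),
        n_groups=g,
        n_samples=n,
        significant=bool(p < SUBTYPE_P_THRESHOLD),
    )


def group_delta(
    cohort: pd.DataFrame,
    label: str,
    group_column: str = "group",
    tumor_tag: str = "tumor",
    normal_tag: str = "normal",
) -> GroupComparison:
    """Tumor-minus-normal difference in mean isoform proportion with a Welch test."""
    sub = _defined(cohort, label)
    x = sub.loc[sub[group_column] == tumor_tag, label].to_numpy(dtype=float)
    y = sub.loc[sub[group_column] == normal_tag, label].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"both groups {tumor_tag!r} and {normal_tag!r} must be present")
    res = welch_ttest(x, y)
    return GroupComparison(
        label=label,
        mean_a=float(np.mean(x)),
        mean_b=float(np.mean(y)),
        delta=float(np.mean(x) - np.mean(y)),
        n_a=len(x),
        n_b=len(y),
        t=res.t,
        df=res.df,
        p=res.p,
    )


def compare_groups(
    cohort: pd.DataFrame,
    labels: list[str],
    group_column: str = "group",
    tumor_tag: str = "tumor",
    normal_tag: str = "normal",
) -> pd.DataFrame:
    """Group deltas for several isoforms, with a BH-adjusted q column.

    The q-values are reported for transparency only; significance flags
    downstream use the raw p-values.
    """
    rows = [
        group_delta(cohort, lab, group_column, tumor_tag, normal_tag) for lab in labels
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    finite = np.isfinite(df["p"].to_numpy(dtype=float))
    q = np.full(len(df), np.nan)
    if finite.any():
        q[finite] = multipletests(df.loc[finite, "p"], method="fdr_bh")[1]
    df["q_bh"] = q
    return df


def trend_test(
    cohort: pd.DataFrame, label: str, time_column: str = "time"
) -> TrendResult:
    """Spearman rank correlation between time and an isoform proportion.

    Requires at least three distinct time points among samples with defined
    proportions; constant proportions yield an undefined (NaN) result.
    """
    sub = _defined(cohort, label)
    t = sub[time_column].to_numpy(dtype=float)
    p_vals = sub[label].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("trend test requires >= 3 distinct time points")
    if np.all(p_vals == p_vals[0]):
        return TrendResult(np.nan, np.nan)
    rho, p = stats.spearmanr(t, p_vals)
    return TrendResult(rho=float(rho), p=float(p))
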