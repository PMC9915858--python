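"""Descriptive and comparative cohort statistics.

Two-group comparisons are normality-gated: each group is screened with the
Shapiro-Wilk test and the groups are compared with Welch's t-test when both
pass, otherwise with the Mann-Whitney U test.  Summaries follow the branch:
mean ± SD for the parametric branch, median and IQR for the rank branch.
Spearman rank correlation (average ranks for ties, pairwise-complete) and a
chi-square test of association round out the layer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mets import BMI_LABELS, bmi_category

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one variable, with the dispatched test."""

    variable: str
    n: tuple[int, int]
    location: tuple[float, float]   # mean or median per group
    scale: tuple[float, float]      # SD or IQR per group
    summary: str                    # "mean_sd" | "median_iqr"
    test: str                       # "t" | "mann-whitney"
    p_value: float


@dataclass(frozen=True)
class CorrelationEntry:
    """Spearman rank correlation for one variable pair."""

    var_a: str
    var_b: str
    rho: float
    p_value: float
    n: int


def normality_gate(values, alpha: float = SHAPIRO_ALPHA) -> bool:
    """Shapiro-Wilk normality screen; True when normality is not rejected.

    Degenerate inputs (n < 3 or a constant vector) fail the gate with a
    warning — the rank-based branch is always available.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3 or np.ptp(x) == 0:
        logger.warning("normality gate failed: degenerate sample (n=%d)", len(x))
        return False
    return bool(sps.shapiro(x).pvalue >= alpha)


def compare_groups(values, groups, variable: str = "", alpha: float = SHAPIRO_ALPHA) -> GroupComparison:
    """Normality-gated two-group comparison of one variable.

    Welch's t-test when both groups pass the Shapiro-Wilk gate at
    ``alpha``; Mann-Whitney U (two-sided, tie-corrected) otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs n >= 3")

    normal = normality_gate(a, alpha) and normality_gate(b, alpha)
    if normal:
        stat = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            variable=variable,
            n=(len(a), len(b)),
            location=(float(a.mean()), float(b.mean())),
            scale=(float(a.std(ddof=1)), float(b.std(ddof=1))),
            summary="mean_sd",
            test="t",
            p_value=float(stat.pvalue),
        )
    stat = sps.mannwhitneyu(a, b, alternative="two-sided")
    iqr = lambda x: float(np.subtract(*np.percentile(x, [75, 25])))
    return GroupComparison(
        variable=variable,
        n=(len(a), len(b)),
        location=(float(np.median(a)), float(np.median(b))),
        scale=(iqr(a), iqr(b)),
        summary="median_iqr",
        test="mann-whitney",
        p_value=float(stat.pvalue),
    )


def compare_table(df: pd.DataFrame, group_col: str, variables: list[str] | None = None) -> pd.DataFrame:
    """Run :func:`compare_groups` over many columns; one row per variable."""
    if variables is None:
        variables = [c for c in df.columns if c != group_col and pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for var in variables:
        try:
            c = compare_groups(df[var], df[group_col], variable=var)
        except ValueError as exc:
            logger.warning("skipping %s: %s", var, exc)
            continue
        rows.append(
            {
                "variable": var,
                "n_group0": c.n[0],
                "n_group1": c.n[1],
                "location_group0": c.location[0],
                "location_group1": c.location[1],
                "scale_group0": c.scale[0],
                "scale_group1": c.scale[1],
                "summary": c.summary,
                "test": c.test,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)


def spearman_matrix(df: pd.DataFrame, variables: list[str] | None = None) -> list[CorrelationEntry]:
    """Spearman correlations for every variable pair, pairwise-complete.

    Constant columns yield a flagged NaN entry rather than an error.
    """
    if variables is None:
        variables = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    entries = []
    for a, b in combinations(variables, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            entries.append(CorrelationEntry(a, b, float("nan"), float("nan"), len(sub)))
            continue
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            logger.warning("spearman undefined for constant column in pair (%s, %s)", a, b)
            entries.append(CorrelationEntry(a, b, float("nan"), float("nan"), len(sub)))
            continue
        res = sps.spearmanr(sub[a], sub[b])
        entries.append(CorrelationEntry(a, b, float(res.statistic), float(res.pvalue), len(sub)))
    return entries


def correlation_frame(entries: list[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in entries])


def trend_by_bmi(panel: pd.DataFrame, bmi_values=None) -> pd.DataFrame:
    """Mean of each index within the four BMI categories, with counts.

    ``panel`` is an index-panel frame; categories come from its ``bmi``
    column unless ``bmi_values`` overrides.  Empty categories are reported
    as missing (NaN means, zero count), never as zeros.
    """
    bmi_vals = panel["bmi"] if bmi_values is None else pd.Series(np.asarray(bmi_values), index=panel.index)
    finite = bmi_vals.notna()
    cats = pd.Series(pd.NA, index=panel.index, dtype=object)
    cats[finite] = bmi_category(bmi_vals[finite].to_numpy())
    cats = pd.Categorical(cats, categories=list(BMI_LABELS), ordered=True)

    value_cols = [c for c in panel.columns if c != "bmi" and pd.api.types.is_numeric_dtype(panel[c])]
    grouped = panel[value_cols].groupby(cats, observed=False).mean()
    counts = pd.Series(cats).value_counts(sort=False).reindex(list(BMI_LABELS)).fillna(0).astype(int)
    out = grouped.copy()
    out.insert(0, "n", counts.to_numpy())
    out.index.name = "bmi_category"
    return out.reset_index()


def sex_association(sex, mets, correction: bool = False) -> tuple[float, float, pd.DataFrame]:
    """Chi-square test of the sex × MetS contingency table.

    Returns (chi2, p, table); Yates continuity correction off by default
    (n ≈ 192 makes it unnecessary), switchable for small strata.
    """
    table = pd.crosstab(pd.Series(sex, name="sex"), pd.Series(mets, name="mets"))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p), table
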