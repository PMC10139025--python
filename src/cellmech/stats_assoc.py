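"""Association statistics over the cell-line summary table.

Regressions (invasiveness or IC50 against mean stiffness), group
comparisons with automatic parametric/non-parametric selection via
Shapiro–Wilk, median dichotomization into high/low groups, Pearson
chi-squared for categorical associations, and housekeeping-normalized
differential expression (per-gene Welch t-tests on log2 values).

``load_table1`` ships the packaged cell-line summary fixture (eight
ovarian cancer lines: morphology, mean stiffness, distribution pattern,
invasiveness score, IC50, CV%).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidConfigError

HOUSEKEEPING_GENES = ("HPRT1", "HMBS", "PPIB")


@dataclass
class AssociationResult:
    kind: str
    statistic: float
    p_value: float
    n: int
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    group_means: dict | None = None
    method: str | None = None


def load_table1() -> pd.DataFrame:
    """Packaged cell-line summary table (one row per line)."""
    with resources.files("cellmech.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def linreg(x, y) -> AssociationResult:
    """Ordinary least squares of y on x: slope, R², two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidConfigError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 for regression")
    res = stats.linregress(x, y)
    return AssociationResult(
        kind="regression",
        statistic=float(res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def compare_groups(values, labels, method: str = "auto") -> AssociationResult:
    """Compare a numeric variable across groups.

    ``auto`` selects a parametric test (Welch t for 2 groups, one-way
    ANOVA for more) when Shapiro–Wilk on the within-group residuals does
    not reject normality at α = 0.05, and a rank test (Wilcoxon rank-sum /
    Kruskal–Wallis) otherwise. Group means are reported alongside.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise InvalidConfigError("values and labels must have equal length")
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if any(v.size < 2 for v in groups.values()):
        raise InsufficientDataError("each group needs n >= 2")
    arrays = list(groups.values())
    if method == "auto":
        resid = np.concatenate([v - v.mean() for v in arrays])
        normal = stats.shapiro(resid).pvalue >= 0.05
        if len(groups) == 2:
            method = "t" if normal else "ranksum"
        else:
            method = "anova" if normal else "kruskal"
    if method == "t":
        res = stats.ttest_ind(*arrays, equal_var=False)
    elif method == "ranksum":
        res = stats.ranksums(*arrays)
    elif method == "anova":
        res = stats.f_oneway(*arrays)
    elif method == "kruskal":
        res = stats.kruskal(*arrays)
    else:
        raise InvalidConfigError(f"unknown method {method!r}")
    return AssociationResult(
        kind="group-comparison",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(values.size),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        method=method,
    )


def dichotomize(values) -> tuple[np.ndarray, float]:
    """Split values at their median into 'high' (> cutoff) and 'low'.

    The cutoff is the sample median (mean of the central pair for even
    n); ties at the cutoff go to 'low'.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need n >= 2 to dichotomize")
    cutoff = float(np.median(values))
    labels = np.where(values > cutoff, "high", "low")
    return labels, cutoff


def chi2_categorical(table) -> AssociationResult:
    """Pearson chi-squared on a contingency table (no Yates correction)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise InvalidConfigError("table must hold non-negative integer counts")
    res = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        kind="chi-squared",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(table.sum()),
    )


def normalize_expression(
    expr: pd.DataFrame,
    housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES,
) -> pd.DataFrame:
    """Divide each gene by the per-sample geometric mean of the
    housekeeping genes (HPRT1, HMBS, PPIB by default)."""
    missing = [g for g in housekeeping if g not in expr.index]
    if missing:
        raise InvalidConfigError(f"housekeeping genes missing: {missing}")
    hk = expr.loc[list(housekeeping)]
    if (hk <= 0).any().any():
        raise InvalidConfigError("housekeeping expression must be positive")
    geo = np.exp(np.log(hk).mean(axis=0))
    return expr.div(geo, axis=1)


def diff_expression(
    normalized: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 normalized expression.

    ``groups`` maps sample name → group label (exactly two levels, each
    with ≥ 2 samples). log2fc is mean(log2 group B) − mean(log2 group A)
    with levels in sorted order. No multiple-testing correction by
    default; the significance flag is p < ``alpha``. Columns: gene,
    log2fc, p_value, significant.
    """
    groups = pd.Series(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise InvalidConfigError("exactly two groups required")
    a_cols = groups.index[groups == levels[0]]
    b_cols = groups.index[groups == levels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    if (normalized[list(a_cols) + list(b_cols)] <= 0).any().any():
        raise InvalidConfigError("expression values must be positive for log2")
    log_a = np.log2(normalized[a_cols].to_numpy(dtype=float))
    log_b = np.log2(normalized[b_cols].to_numpy(dtype=float))
    t, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    log2fc = log_b.mean(axis=1) - log_a.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": normalized.index,
            "log2fc": log2fc,
            "p_value": p,
            "significant": p < alpha,
        }
    ).reset_index(drop=True)
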