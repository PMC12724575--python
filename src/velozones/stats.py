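"""Cohort comparison statistics: normality-gated Welch t vs Mann-Whitney U.

Each metric is compared between the two cohorts with a Welch two-sample
t-test when both groups pass a Shapiro-Wilk normality check, and a
two-sided Mann-Whitney U test otherwise (exact null distribution when the
combined sample is small and tie-free, the tie-corrected normal
approximation elsewhere).  Summary-statistic Welch tests reproduce p-values
from published mean/SD/n rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "compare_groups", "welch_from_summary", "compare_table"]

logger = logging.getLogger(__name__)

ALPHA_NORMALITY = 0.05
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison with its gating diagnostics."""

    metric: str
    test_used: str  # "welch_t" or "mann_whitney_u"
    statistic: float
    p_value: float
    group_summaries: tuple[tuple[float, float, int], tuple[float, float, int]]
    normality_p: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _summary(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), int(len(x))


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; NaN for constant samples (normality undefined)."""
    if np.ptp(x) == 0:
        return float("nan")
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    x: np.ndarray,
    y: np.ndarray,
    alpha_norm: float = ALPHA_NORMALITY,
    metric: str = "",
    test: str = "auto",
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group at ``alpha_norm``; both normal -> Welch t
    (unequal variances, two-sided); otherwise Mann-Whitney U.  Constant
    samples make normality undefined and fall through to Mann-Whitney.
    ``test`` overrides the gate ("welch_t" or "mann_whitney_u").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    px, py = _shapiro_p(x), _shapiro_p(y)
    if test == "welch_t":
        normal = True
    elif test == "mann_whitney_u":
        normal = False
    elif np.isnan(px) or np.isnan(py):
        logger.info("constant sample in %r: normality undefined, using Mann-Whitney", metric)
        normal = False
    else:
        normal = px >= alpha_norm and py >= alpha_norm
    if normal:
        res = sps.ttest_ind(x, y, equal_var=False)
        test_used, stat, p = "welch_t", float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([x, y])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and not ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test_used, stat, p = "mann_whitney_u", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        metric=metric,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        group_summaries=(_summary(x), _summary(y)),
        normality_p=(px, py),
    )


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, metric: str = ""
) -> ComparisonResult:
    """Welch t-test (Welch-Satterthwaite df) from summary statistics alone."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return ComparisonResult(
        metric=metric,
        test_used="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=((mean1, sd1, n1), (mean2, sd2, n2)),
        normality_p=(float("nan"), float("nan")),
    )


def compare_table(
    table: pd.DataFrame,
    group_col: str = "sex",
    metrics: list[str] | None = None,
    alpha_norm: float = ALPHA_NORMALITY,
    holm: bool = False,
) -> pd.DataFrame:
    """Compare every metric column between the two groups of ``table``.

    One row per metric with group summaries, the test used (the field's
    convention marks Mann-Whitney rows with a mu), and the two-sided p.
    ``holm`` adds Holm-adjusted p-values; per-zone reporting without
    correction is the default.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups to compare")
    g1, g2 = groups
    if metrics is None:
        metrics = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for m in metrics:
        r = compare_groups(
            table.loc[table[group_col] == g1, m].to_numpy(),
            table.loc[table[group_col] == g2, m].to_numpy(),
            alpha_norm=alpha_norm,
            metric=m,
        )
        (m1, s1, n1), (m2, s2, n2) = r.group_summaries
        rows.append(
            {
                "metric": m,
                f"{g1}_mean": m1, f"{g1}_sd": s1, f"{g1}_n": n1,
                f"{g2}_mean": m2, f"{g2}_sd": s2, f"{g2}_n": n2,
                "test": r.test_used,
                "marker": "u" if r.test_used == "mann_whitney_u" else "",
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


def render_comparison(table: pd.DataFrame, g1: str, g2: str, title: str = "") -> str:
    """Plain-text rendering of a comparison table (mean +/- SD per group, p)."""
    lines = [title] if title else []
    lines.append(f"{'metric':<34}{g1:>22}{g2:>22}{'p':>9}")
    for _, r in table.iterrows():
        mark = " (u)" if r["marker"] else ""
        lines.append(
            f"{r['metric']:<34}"
            f"{r[f'{g1}_mean']:>12.2f} ± {r[f'{g1}_sd']:>7.2f}"
            f"{r[f'{g2}_mean']:>12.2f} ± {r[f'{g2}_sd']:>7.2f}"
            f"{r['p_value']:>9.3f}{mark}"
        )
    return "\n".join(lines)
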