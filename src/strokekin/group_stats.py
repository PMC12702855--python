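"""Two-group comparison pipeline for the biomarker table.

Per feature: a Shapiro-Wilk normality gate on each group selects between the
pooled-variance two-sample t-test (both groups normal) and the Mann-Whitney
U test; descriptives follow the test choice (mean +/- SD vs median (IQR));
all raw p values are Benjamini-Hochberg adjusted in one 112-test family and
effect sizes are reported as Cohen's d with (n-1)-weighted pooled SD, with
the healthy group first so that a larger patient value yields d > 0.

The Mann-Whitney p value uses the normal approximation with tie correction
and no continuity correction; an exact p is available for small samples.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import schema
from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    StrokekinError,
)

__all__ = [
    "choose_test",
    "two_group_test",
    "t_test_from_summary",
    "mann_whitney",
    "cohens_d",
    "bh_fdr",
    "compare_cohorts",
    "percent_reduction",
    "chi2_test",
]


def choose_test(values_a, values_b, alpha: float = 0.05) -> str:
    """``"t"`` if both groups pass Shapiro-Wilk normality at ``alpha``, else
    ``"mann_whitney"``."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("normality gate needs n >= 3 per group")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return "mann_whitney"  # Shapiro undefined on constant input
    p_a = stats.shapiro(a).pvalue
    p_b = stats.shapiro(b).pvalue
    return "t" if (p_a > alpha and p_b > alpha) else "mann_whitney"


def t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Pooled-variance two-sided t-test from summary statistics.

    Returns ``(p, t)``; usable directly on published mean/SD/n rows.
    """
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(res.pvalue), float(res.statistic)


def mann_whitney(values_a, values_b, exact: bool = False) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(p, U_a)``.

    ``U_a`` counts pairs where a value from group a exceeds one from group b,
    plus half the ties.  The asymptotic p uses the normal approximation with
    tie-corrected variance and no continuity correction; with all
    observations tied the variance vanishes and p = 1.  ``exact=True`` uses
    the exact null distribution (small samples, no ties).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    n_a, n_b = a.size, b.size
    if n_a < 1 or n_b < 1:
        raise InsufficientDataError("Mann-Whitney needs both groups non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.pvalue), u_a
    n = n_a + n_b
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return 1.0, u_a
    z = (u_a - n_a * n_b / 2.0) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z)))), u_a


def two_group_test(values_a, values_b, test: str) -> tuple[float, float]:
    """Run the selected two-sided test; returns ``(p_raw, statistic)``.

    ``test="t"`` is the pooled-variance Student t-test and raises
    :class:`DegenerateDataError` when the pooled variance is zero;
    ``test="mann_whitney"`` is the tie-corrected normal-approximation U test.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("t-test needs n >= 2 per group")
        pooled = (a.var(ddof=1) * (a.size - 1) + b.var(ddof=1) * (b.size - 1))
        if pooled == 0.0:
            raise DegenerateDataError("zero pooled variance: t-test undefined")
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.pvalue), float(res.statistic)
    if test == "mann_whitney":
        return mann_whitney(a, b)
    raise ValueError(f"unknown test {test!r}")


def cohens_d(values_a, values_b) -> float:
    """Cohen's d = (mean_b - mean_a) / s_pooled with (n-1)-weighted pooled SD.

    Convention: a = healthy, b = patient, so a larger patient value gives
    d > 0 (trunk displacement) and a more negative one gives d < 0 (SPARC).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Cohen's d needs n >= 2 per group")
    s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if s2 == 0.0:
        raise DegenerateDataError("zero pooled SD: Cohen's d undefined")
    return float((b.mean() - a.mean()) / math.sqrt(s2))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving, <= 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_reduction(reference: float, value: float) -> float:
    """Percent deficit of ``value`` relative to ``reference``: 100 (1 - v/r)."""
    if reference == 0:
        raise DegenerateDataError("reference value must be nonzero")
    return 100.0 * (1.0 - value / reference)


def chi2_test(counts_a, counts_b) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k contingency table (category counts per
    group); returns ``(p, chi2)``.  Used for categorical demographics."""
    table = np.array([counts_a, counts_b], float)
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue), float(res.statistic)


# ---------------------------------------------------------------------------


def _describe(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q3 - q1:.2f})"


def compare_cohorts(
    table: pd.DataFrame,
    group_a: str = "control",
    group_b: str = "patient",
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison report (one row per biomarker).

    ``table`` is a per-subject feature table with a ``group`` column;
    ``group_a`` is the healthy reference.  FDR adjustment spans all features
    as one family.  Columns mirror the published report layout:
    ``feature, desc_healthy, desc_patient, p_raw, p_adj, cohens_d,
    test_used, significant``.
    """
    features = list(features) if features is not None else list(schema.FEATURE_NAMES)
    missing = sorted(set(features) - set(table.columns))
    if missing:
        raise InsufficientDataError(f"features absent from table: {missing}")
    mask_a = table["group"] == group_a
    mask_b = table["group"] == group_b
    if not mask_a.any() or not mask_b.any():
        raise InsufficientDataError(f"empty group: {group_a!r} or {group_b!r}")

    rows = []
    for feat in features:
        a = table.loc[mask_a, feat].to_numpy(float)
        b = table.loc[mask_b, feat].to_numpy(float)
        try:
            test = choose_test(a, b, alpha)
            p_raw, statistic = two_group_test(a, b, test)
            d = cohens_d(a, b)
        except StrokekinError as exc:
            exc.args = (f"{feat}: {exc.args[0]}",) + exc.args[1:]
            raise
        normal = test == "t"
        rows.append(
            {
                "feature": feat,
                "desc_healthy": _describe(a, normal),
                "desc_patient": _describe(b, normal),
                "p_raw": p_raw,
                "statistic": statistic,
                "cohens_d": d,
                "test_used": test,
            }
        )
    report = pd.DataFrame(rows)
    report["p_adj"] = bh_fdr(report["p_raw"].to_numpy())
    report["significant"] = report["p_adj"] < fdr_q
    return report[
        [
            "feature",
            "desc_healthy",
            "desc_patient",
            "p_raw",
            "p_adj",
            "cohens_d",
            "test_used",
            "significant",
            "statistic",
        ]
    ]
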