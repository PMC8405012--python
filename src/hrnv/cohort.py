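"""Two-group baseline comparisons: normality-gated continuous tests,
categorical tests with the expected-count rule, and median imputation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "ks_normality",
    "compare_continuous",
    "t_test_from_summary",
    "chi2_yates",
    "fisher_exact",
    "median_impute",
    "baseline_table",
    "format_p",
]

NORMALITY_ALPHA = 0.05
MIN_EXPECTED_FOR_CHI2 = 5.0


@dataclass
class GroupComparison:
    variable: str
    test_used: str  # one of: t, mann_whitney, chi2_yates, fisher
    statistic: float
    p_value: float
    summary_a: str = ""
    summary_b: str = ""
    flags: dict = field(default_factory=dict)


def format_p(p: float) -> str:
    """Three decimals, '<0.001' below 0.0005."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


def ks_normality(values, alpha: float = NORMALITY_ALPHA) -> tuple:
    """Lilliefors-style KS normality p-value and a normal/non-normal verdict.

    Location and scale are estimated from the data.  Fewer than 5 usable
    values, or zero variance, is inconclusive and treated as non-normal.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5 or np.std(x, ddof=1) == 0:
        return np.nan, False
    _, p = lilliefors(x, dist="norm")
    return float(p), bool(p >= alpha)


def compare_continuous(a_values, b_values, variable: str = "") -> GroupComparison:
    """Two-group comparison gated on normality of both groups.

    Both normal: two-tailed pooled t-test, summaries mean (SD).  Otherwise:
    Mann-Whitney U with the normal (midrank tie-corrected) approximation,
    summaries median (IQR).
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 non-missing values")
    flags: dict = {}
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        flags["degenerate"] = "zero variance in both groups with equal means"
        return GroupComparison(variable, "t", 0.0, 1.0, flags=flags)

    _, a_normal = ks_normality(a)
    _, b_normal = ks_normality(b)
    if a_normal and b_normal:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        summ = [f"{g.mean():.1f} ({g.std(ddof=1):.1f})" for g in (a, b)]
        return GroupComparison(variable, "t", float(stat), float(p), *summ, flags)
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    summ = [
        f"{np.median(g):.1f} ({np.percentile(g, 25):.1f}-{np.percentile(g, 75):.1f})"
        for g in (a, b)
    ]
    return GroupComparison(variable, "mann_whitney", float(stat), float(p), *summ, flags)


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    pooled: bool = True,
) -> tuple:
    """Two-sample two-sided t-test from summary statistics.

    Pooled-variance Student t by default; Welch with ``pooled=False``.
    Returns (statistic, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        return (0.0, 1.0) if mean1 == mean2 else (np.inf, 0.0)
    if pooled:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_yates(table) -> tuple:
    """Continuity-corrected Pearson chi-square on a 2x2 table, df = 1.

    Returns (statistic, p).  The correction is floored so over-correction
    cannot produce a negative statistic.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi2_yates expects a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined: a margin of the table is zero")
    expected = np.outer(row, col) / total
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float(np.sum(adj**2 / expected))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("fisher_exact expects a non-negative 2x2 table")
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return float(p)


def median_impute(
    cohort: pd.DataFrame,
    continuous: list | None = None,
    categorical: list | None = None,
    max_missing_fraction: float = 0.05,
) -> tuple:
    """Fill missing cells: column median (continuous) or mode (categorical).

    Returns ``(imputed_frame, log)`` where the log lists one entry per
    imputed cell.  A fully missing column, or one whose missingness exceeds
    the cap, raises.
    """
    frame = cohort.copy()
    if continuous is None and categorical is None:
        continuous = [c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])]
        categorical = [c for c in frame.columns if c not in continuous]
    continuous = continuous or []
    categorical = categorical or []
    log = []
    for col in [*continuous, *categorical]:
        miss = frame[col].isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if miss.mean() > max_missing_fraction:
            raise ValueError(
                f"column {col!r} missing fraction {miss.mean():.3f} exceeds cap "
                f"{max_missing_fraction}"
            )
        fill = frame.loc[~miss, col].median() if col in continuous else frame.loc[~miss, col].mode().iloc[0]
        for idx in frame.index[miss]:
            log.append({"column": col, "index": idx, "value": fill})
        frame.loc[miss, col] = fill
    return frame, log


def baseline_table(
    cohort: pd.DataFrame,
    outcome_col: str = "outcome",
    continuous: list | None = None,
    categorical: list | None = None,
) -> pd.DataFrame:
    """One comparison row per variable, split on the binary outcome.

    Continuous variables go through the normality gate; binary categorical
    variables use Yates chi-square when all expected counts are >= 5 and
    Fisher's exact test otherwise.
    """
    y = cohort[outcome_col]
    if y.nunique() < 2:
        raise ValueError("outcome must have both classes for a baseline table")
    a = cohort[y == 0]
    b = cohort[y == 1]

    if continuous is None and categorical is None:
        continuous, categorical = [], []
        for col in cohort.columns:
            if col == outcome_col or not pd.api.types.is_numeric_dtype(cohort[col]):
                continue
            (categorical if set(cohort[col].dropna().unique()) <= {0, 1} else continuous).append(col)

    rows = []
    for col in continuous or []:
        gc = compare_continuous(a[col], b[col], variable=col)
        rows.append(gc)
    for col in categorical or []:
        table = np.array(
            [
                [(a[col] == 1).sum(), (a[col] == 0).sum()],
                [(b[col] == 1).sum(), (b[col] == 0).sum()],
            ],
            dtype=float,
        )
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if np.any(expected < MIN_EXPECTED_FOR_CHI2):
            p = fisher_exact(table)
            gc = GroupComparison(col, "fisher", np.nan, p)
        else:
            stat, p = chi2_yates(table)
            gc = GroupComparison(col, "chi2_yates", stat, p)
        gc.summary_a = f"{int(table[0, 0])} ({100 * table[0, 0] / table[0].sum():.1f})"
        gc.summary_b = f"{int(table[1, 0])} ({100 * table[1, 0] / table[1].sum():.1f})"
        rows.append(gc)

    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "test": [r.test_used for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "p_formatted": [format_p(r.p_value) for r in rows],
            "group0": [r.summary_a for r in rows],
            "group1": [r.summary_b for r in rows],
        }
    )
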