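"""Variable selection and logistic modelling.

Implements the three-stage procedure: a univariable logistic screen,
iterative collinearity pruning keyed on screen p-values, and backward
stepwise multivariable logistic regression with Wald-p elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LogisticFit",
    "ScreenResult",
    "StepwiseTrace",
    "PipelineConfig",
    "fit_logistic",
    "univariable_screen",
    "collinearity_prune",
    "backward_stepwise",
    "build_hrnv_model",
]

SCREEN_P = 0.2
COLLINEARITY_R = 0.8
P_REMOVE = 0.1
#: |coefficient| beyond this is treated as a separation artefact
SEPARATION_COEF_LIMIT = 15.0

ADJUSTMENT_VARS = ("age", "temperature", "sbp", "heart_rate", "gcs")


@dataclass
class LogisticFit:
    """Per-variable coefficient table of one maximum-likelihood fit."""

    variables: list
    coefs: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int
    flags: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "coef": self.coefs,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )

    def wald_p(self, variable: str) -> float:
        return float(self.p_values[self.variables.index(variable)])


@dataclass
class ScreenResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    passes_screen: bool
    flags: dict = field(default_factory=dict)


@dataclass
class StepwiseTrace:
    """Removal ledger plus the retained set and its final fit."""

    removed: list  # ordered (variable, wald p at removal)
    retained: list
    final_fit: LogisticFit | None
    dropped_unestimable: list = field(default_factory=list)

    def partition_ok(self, candidates) -> bool:
        ledger = {v for v, _ in self.removed} | set(self.retained) | set(self.dropped_unestimable)
        disjoint = (
            len(self.removed) + len(self.retained) + len(self.dropped_unestimable) == len(ledger)
        )
        return disjoint and ledger == set(candidates)


def fit_logistic(design: pd.DataFrame, outcome, add_intercept: bool = True) -> LogisticFit:
    """ML logistic fit with OR = exp(coef) and Wald 95% CIs / p-values.

    Perfect separation or non-identifiable columns are flagged per variable
    (unestimable) instead of raising.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("logistic fit needs at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    flags: dict = {}
    for col in X.columns:
        if X[col].std() == 0:
            flags[col] = "unestimable: no variation"
    estimable = [c for c in X.columns if c not in flags]
    if not estimable:
        raise ValueError("no estimable predictors")
    Xe = X[estimable]
    M = sm.add_constant(Xe, has_constant="add") if add_intercept else Xe

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, M).fit(disp=0, maxiter=200, method="newton", tol=1e-8)
        except Exception:
            try:
                result = sm.Logit(y, M).fit(disp=0, maxiter=500, method="bfgs")
            except Exception as exc:  # pragma: no cover - pathological designs
                raise ValueError(f"logistic fit failed: {exc}") from None
        converged = bool(result.mle_retvals.get("converged", True))

    params = result.params
    bse = result.bse
    names, coefs, ses = [], [], []
    for name in M.columns:
        if name == "const":
            continue
        c, s = float(params[name]), float(bse[name])
        if not np.isfinite(s) or abs(c) > SEPARATION_COEF_LIMIT:
            flags[name] = "unestimable: separation suspected"
        names.append(name)
        coefs.append(c)
        ses.append(s)
    coefs = np.asarray(coefs)
    ses = np.asarray(ses)
    z = np.divide(coefs, ses, out=np.zeros_like(coefs), where=ses > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # separation fits can overflow exp harmlessly
        return _make_fit(names, coefs, ses, p, converged, X.shape[0], flags)


def _make_fit(names, coefs, ses, p, converged, n_obs, flags) -> LogisticFit:
    return LogisticFit(
        variables=names,
        coefs=coefs,
        standard_errors=ses,
        odds_ratios=np.exp(coefs),
        ci_low=np.exp(coefs - 1.96 * ses),
        ci_high=np.exp(coefs + 1.96 * ses),
        p_values=p,
        converged=converged,
        n_obs=n_obs,
        flags=flags,
    )


def univariable_screen(
    features: pd.DataFrame, outcome, threshold: float = SCREEN_P
) -> list:
    """One single-predictor logistic fit per column; per-variable failures
    are flagged and the screen continues."""
    results = []
    for col in features.columns:
        try:
            fit = fit_logistic(features[[col]], outcome)
        except ValueError as exc:
            results.append(
                ScreenResult(col, np.nan, np.nan, np.nan, np.nan, False, {"error": str(exc)})
            )
            continue
        p = fit.wald_p(col)
        flagged = {k: v for k, v in fit.flags.items() if k == col}
        results.append(
            ScreenResult(
                variable=col,
                odds_ratio=float(fit.odds_ratios[0]),
                ci_low=float(fit.ci_low[0]),
                ci_high=float(fit.ci_high[0]),
                p_value=p,
                passes_screen=bool(np.isfinite(p) and p < threshold and not flagged),
                flags=flagged,
            )
        )
    return results


def screen_table(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "passes_screen": [r.passes_screen for r in results],
        }
    )


def collinearity_prune(
    features: pd.DataFrame,
    screen: list,
    r_threshold: float = COLLINEARITY_R,
) -> tuple:
    """Iteratively drop one member of each collinear pair.

    The most collinear pair is resolved first; within a pair the member with
    the larger univariable p goes (ties: lexicographically later name).
    Returns ``(retained_names, elimination_log)``.
    """
    p_of = {r.variable: (r.p_value if np.isfinite(r.p_value) else np.inf) for r in screen}
    current = [c for c in features.columns if c in p_of]
    log = []
    while len(current) > 1:
        corr = features[current].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if np.nanmax(corr) < r_threshold:
            break
        # deterministic choice: strongest |r|, ties by variable-name pair
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        a, b = sorted((current[i], current[j]))
        if (p_of[a], a) >= (p_of[b], b):
            drop, keep = a, b
        else:
            drop, keep = b, a
        log.append({"dropped": drop, "kept": keep, "abs_r": float(corr[i, j])})
        current.remove(drop)
    return current, log


def backward_stepwise(
    candidates: pd.DataFrame,
    outcome,
    p_remove: float = P_REMOVE,
    force_vars: tuple = (),
) -> StepwiseTrace:
    """Backward elimination on Wald p-values.

    Fits the full model, then repeatedly removes the single largest-p
    variable at or above ``p_remove`` and refits; removed variables never
    re-enter.  Unestimable variables in the full model are dropped first and
    logged.  ``force_vars`` are exempt from elimination.
    """
    y = np.asarray(outcome, dtype=float)
    current = list(candidates.columns)
    if len(current) >= candidates.shape[0] / 2:
        raise ValueError("too many candidates for the sample size (need count < n/2)")

    fit = fit_logistic(candidates[current], y)
    dropped_unestimable = [v for v in current if v in fit.flags]
    for v in dropped_unestimable:
        current.remove(v)
    if dropped_unestimable:
        fit = fit_logistic(candidates[current], y) if current else None

    removed: list = []
    while current and fit is not None:
        removable = [v for v in current if v not in force_vars]
        if not removable:
            break
        ps = {v: fit.wald_p(v) for v in removable}
        worst = max(ps, key=lambda v: (ps[v], v))
        if ps[worst] < p_remove:
            break
        removed.append((worst, float(ps[worst])))
        current.remove(worst)
        fit = fit_logistic(candidates[current], y) if current else None

    return StepwiseTrace(
        removed=removed,
        retained=current,
        final_fit=fit,
        dropped_unestimable=dropped_unestimable,
    )


@dataclass(frozen=True)
class PipelineConfig:
    screen_p: float = SCREEN_P
    collinearity_r: float = COLLINEARITY_R
    p_remove: float = P_REMOVE
    adjust_vars: tuple = ADJUSTMENT_VARS
    force_vars: tuple = ()  # adjustment variables eligible for removal by default


@dataclass
class ModelReport:
    screen: list
    pruned: list
    prune_log: list
    trace: StepwiseTrace

    @property
    def final_table(self) -> pd.DataFrame:
        return self.trace.final_fit.table() if self.trace.final_fit else pd.DataFrame()


def build_hrnv_model(
    cohort: pd.DataFrame,
    feature_cols: list,
    outcome_col: str = "outcome",
    config: PipelineConfig | None = None,
) -> ModelReport:
    """Full selection pipeline on a cohort table.

    Variability features are screened at ``screen_p``; the clinical
    adjustment variables join the survivors unconditionally; the combined
    set is collinearity-pruned and fed to backward stepwise elimination.
    """
    config = config or PipelineConfig()
    y = cohort[outcome_col]

    screen = univariable_screen(cohort[feature_cols], y, threshold=config.screen_p)
    survivors = [r.variable for r in screen if r.passes_screen]

    adjust = [v for v in config.adjust_vars if v in cohort.columns and v not in survivors]
    screen_adjust = univariable_screen(cohort[adjust], y, threshold=config.screen_p) if adjust else []
    all_screen = screen + screen_adjust
    pool = survivors + adjust

    pruned, prune_log = collinearity_prune(
        cohort[pool], all_screen, r_threshold=config.collinearity_r
    )
    trace = backward_stepwise(
        cohort[pruned], y, p_remove=config.p_remove, force_vars=config.force_vars
    )
    return ModelReport(screen=all_screen, pruned=pruned, prune_log=prune_log, trace=trace)
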