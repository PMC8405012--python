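"""Cross-validated ROC evaluation and early-warning-score comparators.

The AUC is the Mann-Whitney pair estimator (ties count one half); its 95%
interval comes from DeLong's covariance by default, with a stratified
bootstrap fallback.  NEWS / MEWS / qSOFA are published lookup-table scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from hrnv.model import ModelReport, PipelineConfig, build_hrnv_model

__all__ = [
    "RocResult",
    "VitalsRecord",
    "auc",
    "auc_ci",
    "roc_points",
    "kfold_out_of_fold_scores",
    "news_score",
    "mews_score",
    "qsofa_score",
    "compare_models",
]


@dataclass
class RocResult:
    label: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    fold_assignment: np.ndarray | None = None
    seed: int | None = None


@dataclass
class VitalsRecord:
    """Triage vitals consumed by the score calculators (None = missing)."""

    resp_rate: float | None = None  # breaths/min
    spo2: float | None = None  # %
    on_oxygen: bool | None = None
    temperature: float | None = None  # Celsius
    sbp: float | None = None  # mmHg
    heart_rate: float | None = None  # bpm
    gcs: float | None = None  # 3-15
    avpu: str | None = None  # A/V/P/U, derived from GCS when absent


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of correctly ordered positive-negative
    pairs, ties counting one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple:
    """95% interval for the AUC: DeLong normal-theory (default) or
    stratified bootstrap percentiles.  Degenerate DeLong variance falls back
    to the bootstrap.  Returns (ci_low, ci_high, method_used)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    point = auc(s, y)
    if method == "delong":
        var = _delong_variance(s, y)
        if var > 0:
            z = stats.norm.ppf(1 - alpha / 2)
            half = z * np.sqrt(var)
            return max(0.0, point - half), min(1.0, point + half), "delong"
        method = "bootstrap"
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        draws[b] = auc(s[idx], y[idx])
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), "bootstrap"


def roc_points(scores, labels) -> tuple:
    """ROC curve: (thresholds, fpr, tpr), monotone in both coordinates."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    cut = np.concatenate([distinct, [y_sorted.size - 1]])
    tps = np.cumsum(y_sorted == 1)[cut]
    fps = np.cumsum(y_sorted == 0)[cut]
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    fpr = np.concatenate([[0.0], fps / n_neg])
    tpr = np.concatenate([[0.0], tps / n_pos])
    return thresholds, fpr, tpr


def kfold_out_of_fold_scores(
    cohort: pd.DataFrame,
    recipe,
    k: int = 10,
    seed: int = 0,
    outcome_col: str = "outcome",
    max_retries: int = 20,
) -> tuple:
    """Out-of-fold predicted probabilities from stratified k-fold CV.

    ``recipe(train_frame) -> scorer`` must return a callable mapping a test
    frame to probabilities; the recipe is re-run inside every training fold
    so any variable selection it performs cannot leak.  Returns
    ``(scores, fold_assignment)``.
    """
    y = cohort[outcome_col].to_numpy()
    n = len(cohort)
    if n < 2 * k:
        raise ValueError(f"need at least 2k = {2 * k} patients for {k}-fold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    for attempt in range(max_retries):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(splitter.split(np.zeros(n), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:
        raise RuntimeError(f"could not build {k} folds with both classes after {max_retries} tries")

    scores = np.full(n, np.nan)
    assignment = np.full(n, -1, dtype=int)
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        scorer = recipe(cohort.iloc[train_idx])
        scores[test_idx] = np.asarray(scorer(cohort.iloc[test_idx]), dtype=float)
        assignment[test_idx] = fold_id
    assert not np.isnan(scores).any(), "every patient must be scored exactly once"
    return scores, assignment


class LogisticRecipe:
    """Plain logistic model on fixed columns (no in-fold selection)."""

    def __init__(self, feature_cols, outcome_col: str = "outcome"):
        self.feature_cols = list(feature_cols)
        self.outcome_col = outcome_col

    def __call__(self, train: pd.DataFrame):
        # near-unpenalized sklearn fit: matches the ML solution on benign
        # folds and stays finite under in-fold perfect separation
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(C=1e6, max_iter=2000)
        model.fit(train[self.feature_cols].to_numpy(dtype=float),
                  train[self.outcome_col].to_numpy(dtype=int))

        def scorer(test: pd.DataFrame) -> np.ndarray:
            return model.predict_proba(test[self.feature_cols].to_numpy(dtype=float))[:, 1]

        return scorer


class SelectionRecipe:
    """Re-runs screen -> prune -> stepwise inside each training fold."""

    def __init__(
        self,
        feature_cols,
        outcome_col: str = "outcome",
        config: PipelineConfig | None = None,
    ):
        self.feature_cols = list(feature_cols)
        self.outcome_col = outcome_col
        self.config = config or PipelineConfig()

    def __call__(self, train: pd.DataFrame):
        report: ModelReport = build_hrnv_model(
            train, self.feature_cols, outcome_col=self.outcome_col, config=self.config
        )
        retained = report.trace.retained
        if not retained:  # null model: constant prevalence score
            p0 = float(train[self.outcome_col].mean())
            return lambda test: np.full(len(test), p0)
        inner = LogisticRecipe(retained, self.outcome_col)
        return inner(train)


# ---------------------------------------------------------------------------
# early-warning scores (published band tables)


def _band(value: float, bands: list) -> int:
    """bands: list of (upper_bound_inclusive, points); last bound is inf."""
    for bound, points in bands:
        if value <= bound:
            return points
    raise AssertionError("band table must terminate with an open bound")


def _avpu_from_gcs(gcs: float) -> str:
    if gcs >= 15:
        return "A"
    if gcs >= 13:
        return "V"
    if gcs >= 9:
        return "P"
    return "U"


def news_score(v: VitalsRecord) -> tuple:
    """National Early Warning Score (scale-1 SpO2 banding).

    Returns ``(score, flags)``; missing components are skipped and flagged
    partial.
    """
    total, flags = 0, {}
    if v.resp_rate is None:
        flags["resp_rate"] = "missing"
    else:
        total += _band(v.resp_rate, [(8, 3), (11, 1), (20, 0), (24, 2), (np.inf, 3)])
    if v.spo2 is None:
        flags["spo2"] = "missing"
    else:
        total += _band(v.spo2, [(91, 3), (93, 2), (95, 1), (np.inf, 0)])
    if v.on_oxygen is None:
        flags["on_oxygen"] = "missing"
    elif v.on_oxygen:
        total += 2
    if v.temperature is None:
        flags["temperature"] = "missing"
    else:
        total += _band(v.temperature, [(35.0, 3), (36.0, 1), (38.0, 0), (39.0, 1), (np.inf, 2)])
    if v.sbp is None:
        flags["sbp"] = "missing"
    else:
        total += _band(v.sbp, [(90, 3), (100, 2), (110, 1), (219, 0), (np.inf, 3)])
    if v.heart_rate is None:
        flags["heart_rate"] = "missing"
    else:
        total += _band(v.heart_rate, [(40, 3), (50, 1), (90, 0), (110, 1), (130, 2), (np.inf, 3)])
    avpu = v.avpu or (_avpu_from_gcs(v.gcs) if v.gcs is not None else None)
    if avpu is None:
        flags["consciousness"] = "missing"
    elif avpu != "A":
        total += 3
    return total, flags


def mews_score(v: VitalsRecord) -> tuple:
    """Modified Early Warning Score.  Returns ``(score, flags)``."""
    total, flags = 0, {}
    if v.sbp is None:
        flags["sbp"] = "missing"
    else:
        total += _band(v.sbp, [(70, 3), (80, 2), (100, 1), (199, 0), (np.inf, 2)])
    if v.heart_rate is None:
        flags["heart_rate"] = "missing"
    else:
        total += _band(v.heart_rate, [(40, 2), (50, 1), (100, 0), (110, 1), (129, 2), (np.inf, 3)])
    if v.resp_rate is None:
        flags["resp_rate"] = "missing"
    else:
        total += _band(v.resp_rate, [(8, 2), (14, 0), (20, 1), (29, 2), (np.inf, 3)])
    if v.temperature is None:
        flags["temperature"] = "missing"
    else:
        total += _band(v.temperature, [(34.9, 2), (38.4, 0), (np.inf, 2)])
    avpu = v.avpu or (_avpu_from_gcs(v.gcs) if v.gcs is not None else None)
    if avpu is None:
        flags["consciousness"] = "missing"
    else:
        total += {"A": 0, "V": 1, "P": 2, "U": 3}[avpu]
    return total, flags


def qsofa_score(v: VitalsRecord) -> tuple:
    """quick SOFA: (RR >= 22) + (SBP <= 100) + (GCS < 15), range 0-3."""
    total, flags = 0, {}
    if v.resp_rate is None:
        flags["resp_rate"] = "missing"
    else:
        total += int(v.resp_rate >= 22)
    if v.sbp is None:
        flags["sbp"] = "missing"
    else:
        total += int(v.sbp <= 100)
    if v.gcs is None:
        flags["gcs"] = "missing"
    else:
        total += int(v.gcs < 15)
    return total, flags


def score_column(cohort: pd.DataFrame, calculator) -> np.ndarray:
    """Apply a score calculator row-wise over cohort vitals columns."""
    out = np.empty(len(cohort))
    for i, (_, row) in enumerate(cohort.iterrows()):
        v = VitalsRecord(
            resp_rate=row.get("resp_rate"),
            spo2=row.get("spo2"),
            on_oxygen=bool(row.get("on_oxygen", False)),
            temperature=row.get("temperature"),
            sbp=row.get("sbp"),
            heart_rate=row.get("heart_rate"),
            gcs=row.get("gcs"),
        )
        out[i], _ = calculator(v)
    return out


def _roc_result(label, scores, y, seed, assignment=None, ci_method="delong") -> RocResult:
    thresholds, fpr, tpr = roc_points(scores, y)
    lo, hi, method = auc_ci(scores, y, method=ci_method, seed=seed or 0)
    return RocResult(
        label=label,
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc(scores, y),
        ci_low=lo,
        ci_high=hi,
        ci_method=method,
        fold_assignment=assignment,
        seed=seed,
    )


def compare_models(
    cohort: pd.DataFrame,
    recipes: dict | None = None,
    score_baselines: dict | None = None,
    k: int = 10,
    seed: int = 0,
    outcome_col: str = "outcome",
) -> dict:
    """One RocResult per entrant on a shared fold structure.

    Fitted-model recipes are evaluated out-of-fold; lookup-score baselines
    are scored directly.  Entrants that fail are excluded with a logged
    reason under the key ``_errors``.
    """
    y = cohort[outcome_col].to_numpy()
    results: dict = {}
    errors: dict = {}
    for label, recipe in (recipes or {}).items():
        try:
            scores, assignment = kfold_out_of_fold_scores(
                cohort, recipe, k=k, seed=seed, outcome_col=outcome_col
            )
            results[label] = _roc_result(label, scores, y, seed, assignment)
        except Exception as exc:
            errors[label] = str(exc)
    for label, calculator in (score_baselines or {}).items():
        try:
            scores = score_column(cohort, calculator)
            results[label] = _roc_result(label, scores, y, seed)
        except Exception as exc:
            errors[label] = str(exc)
    if errors:
        results["_errors"] = errors
    return results
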