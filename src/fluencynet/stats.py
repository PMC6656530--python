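"""Group comparisons and diagnosis-prediction models for cohort tables.

The cohort table has one row per participant network (participant x
diagnosis), with behavioural scores (responses per list, perseveration
rate), the network measures and their mock-ensemble deltas, the fitted
p_emit, and covariates.  This module provides the variance-gated two-sample
t test, logistic diagnosis models with AIC-based bidirectional stepwise
selection, and stratified split-half cross-validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .corpus import FluencyCorpus, FluencyList
from .errors import DegenerateDataError, EstimationError

__all__ = [
    "perseveration_rate",
    "corpus_perseveration_rate",
    "TTestResult",
    "group_ttest",
    "ModelFit",
    "fit_logistic",
    "stepwise_aic",
    "CVResult",
    "split_half_cv",
    "ConfusionSummary",
    "confusion_summary",
]


def perseveration_rate(fluency_list: FluencyList) -> float:
    """Fraction of responses that repeat an earlier response in the same list."""
    n = len(fluency_list.items)
    return fluency_list.n_perseverations / n


def corpus_perseveration_rate(corpus: FluencyCorpus) -> float:
    """Mean per-list perseveration rate of one participant."""
    return float(np.mean([perseveration_rate(fl) for fl in corpus.lists]))


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    welch: bool
    f_statistic: float
    f_pvalue: float


def group_ttest(x: Sequence[float], y: Sequence[float], var_alpha: float = 0.05) -> TTestResult:
    """Two-sample comparison, Welch-corrected when an F test rejects equal variances.

    The two-sided F test at ``var_alpha`` decides between the pooled-variance
    and Welch t statistics; the result records which branch was used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each group needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateDataError("both groups have zero variance")
    f_stat = vx / vy if vy > 0 else math.inf
    if math.isinf(f_stat):
        f_p = 0.0
    else:
        cdf = sps.f.cdf(f_stat, len(x) - 1, len(y) - 1)
        f_p = float(2 * min(cdf, 1 - cdf))
    welch = f_p < var_alpha
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        welch=welch,
        f_statistic=float(f_stat),
        f_pvalue=f_p,
    )


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood binomial fit (intercept + main effects)."""

    factors: tuple[str, ...]
    params: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    aic: float
    null_deviance: float
    deviance: float
    separation: bool
    nobs: int

    @property
    def n_parameters(self) -> int:
        return len(self.factors) + 1


def _design(table: pd.DataFrame, factors: Sequence[str], outcome: str, positive: str):
    missing = [f for f in factors if f not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks factor column(s) {missing}")
    x = table[list(factors)].astype(float)
    if x.isna().any().any():
        bad = x.columns[x.isna().any()].tolist()
        raise ValueError(f"missing values among factors {bad}")
    y = (table[outcome] == positive).astype(float)
    if y.nunique() < 2:
        raise DegenerateDataError("outcome must contain both classes")
    return sm.add_constant(x, has_constant="add"), y


def _fit_binomial(x: pd.DataFrame, y: pd.Series):
    """Logit fit that survives perfect separation, flagging it instead of raising."""
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            res = sm.Logit(y, x).fit(method="bfgs", maxiter=1000, disp=0)
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            separation = True
    return res, separation


def fit_logistic(
    table: pd.DataFrame,
    factors: Sequence[str],
    outcome: str = "diagnosis",
    positive: str = "PAD",
) -> ModelFit:
    """Binomial GLM of diagnosis on main effects (no interactions)."""
    x, y = _design(table, factors, outcome, positive)
    res, separation = _fit_binomial(x, y)
    names = list(x.columns)
    return ModelFit(
        factors=tuple(factors),
        params=dict(zip(names, map(float, np.asarray(res.params)))),
        zvalues=dict(zip(names, map(float, np.asarray(res.tvalues)))),
        pvalues=dict(zip(names, map(float, np.asarray(res.pvalues)))),
        aic=float(res.aic),
        null_deviance=float(-2.0 * res.llnull),
        deviance=float(-2.0 * res.llf),
        separation=separation,
        nobs=int(res.nobs),
    )


def stepwise_aic(
    table: pd.DataFrame,
    start_factors: Sequence[str],
    candidate_factors: Sequence[str],
    outcome: str = "diagnosis",
    positive: str = "PAD",
) -> ModelFit:
    """Bidirectional stepwise selection minimizing AIC.

    Repeats until no single-factor removal or addition lowers AIC; the best
    move is applied each round, deterministically given the table.
    """
    candidates = list(dict.fromkeys(candidate_factors))
    if not set(start_factors) <= set(candidates):
        raise ValueError("candidate_factors must include every start factor")
    current = list(dict.fromkeys(start_factors))
    current_fit = fit_logistic(table, current, outcome, positive)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for f in current:
            if len(current) > 1:
                moves.append((math.nan, [g for g in current if g != f]))
        for f in candidates:
            if f not in current:
                moves.append((math.nan, current + [f]))
        best_fit = None
        best_factors = None
        for _, trial in moves:
            fit = fit_logistic(table, trial, outcome, positive)
            if best_fit is None or fit.aic < best_fit.aic:
                best_fit, best_factors = fit, trial
        if best_fit is not None and best_fit.aic < current_fit.aic - 1e-9:
            current, current_fit = best_factors, best_fit  # type: ignore[assignment]
        else:
            return current_fit


@dataclass(frozen=True)
class ConfusionSummary:
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_summary(
    hits: float, misses: float, false_alarms: float, correct_rejections: float
) -> ConfusionSummary:
    """Accuracy, precision, recall and F1 from (possibly averaged) confusion counts."""
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    total = hits + misses + false_alarms + correct_rejections
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    accuracy = (hits + correct_rejections) / total
    precision = hits / (hits + false_alarms) if hits + false_alarms > 0 else math.nan
    recall = hits / (hits + misses) if hits + misses > 0 else math.nan
    if not math.isnan(precision) and not math.isnan(recall) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = math.nan
    return ConfusionSummary(accuracy, precision, recall, f1)


@dataclass(frozen=True)
class CVResult:
    """Split-half cross-validation summary (confusion counts averaged per rep)."""

    hits: float
    misses: float
    false_alarms: float
    correct_rejections: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    n_reps: int
    n_skipped: int


def split_half_cv(
    table: pd.DataFrame,
    factors: Sequence[str],
    n_reps: int = 5000,
    rng: np.random.Generator | None = None,
    outcome: str = "diagnosis",
    positive: str = "PAD",
    threshold: float = 0.5,
) -> CVResult:
    """Stratified split-half cross-validation of a fixed-factor logistic model.

    Each repetition splits the rows in half preserving the class ratio, fits
    on one half, and scores predictions on the other at ``threshold``.
    Repetitions whose training half cannot be fit are skipped and counted.
    """
    rng = np.random.default_rng() if rng is None else rng
    x_all, y_all = _design(table, factors, outcome, positive)
    x_mat = x_all.to_numpy()
    y_vec = y_all.to_numpy()
    class_idx = [np.flatnonzero(y_vec == c) for c in (0.0, 1.0)]
    counts = np.zeros(4)  # hits, misses, false alarms, correct rejections
    n_done = 0
    n_skipped = 0
    for _ in range(n_reps):
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for idx in class_idx:
            perm = rng.permutation(idx)
            half = len(idx) - len(idx) // 2  # ceil: odd classes favour training
            train_idx.append(perm[:half])
            test_idx.append(perm[half:])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        if len(np.unique(y_vec[tr])) < 2 or len(te) == 0:
            n_skipped += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y_vec[tr], x_mat[tr]).fit(disp=0, maxiter=200)
                params = np.asarray(res.params)
        except Exception:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y_vec[tr], x_mat[tr]).fit(
                        method="bfgs", maxiter=500, disp=0
                    )
                    params = np.asarray(res.params)
            except Exception:
                n_skipped += 1
                continue
        eta = x_mat[te] @ params
        pred = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))) > threshold
        actual = y_vec[te] == 1.0
        counts[0] += np.sum(pred & actual)
        counts[1] += np.sum(~pred & actual)
        counts[2] += np.sum(pred & ~actual)
        counts[3] += np.sum(~pred & ~actual)
        n_done += 1
    if n_done == 0:
        raise EstimationError("every cross-validation repetition failed")
    counts /= n_done
    summary = confusion_summary(*counts)
    return CVResult(
        hits=float(counts[0]),
        misses=float(counts[1]),
        false_alarms=float(counts[2]),
        correct_rejections=float(counts[3]),
        accuracy=summary.accuracy,
        precision=summary.precision,
        recall=summary.recall,
        f1=summary.f1,
        n_reps=n_done,
        n_skipped=n_skipped,
    )
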