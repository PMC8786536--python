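"""Clinical validation statistics for a candidate marker.

Covers immunohistochemistry score dichotomization (1-2 low / 3-4 high),
2x2 chi-squared association with clinicopathological strata (with or
without Yates continuity correction), Kaplan-Meier curves, the
two-group log-rank test, univariate and multivariate Cox
proportional-hazards regression (Efron tie handling), and a plain
rank-based ROC AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"


def dichotomize(values, rule: str = "ihc") -> pd.Series:
    """Label values low/high.

    ``rule="ihc"``: integer staining scores, 1-2 -> low, 3-4 -> high.
    ``rule="median"`` (or any float quantile via ``rule=0.5`` etc.):
    values <= the cut point -> low (ties at the cut go to low).
    """
    s = pd.Series(values)
    if rule == "ihc":
        scores = s.astype(int)
        if not scores.isin([1, 2, 3, 4]).all():
            raise ValueError("IHC staining scores must be in {1, 2, 3, 4}")
        return scores.map(lambda x: LOW if x <= 2 else HIGH)
    q = 0.5 if rule == "median" else float(rule)
    cut = s.quantile(q)
    labels = s.map(lambda x: LOW if x <= cut else HIGH)
    if labels.nunique() == 1:
        logger.warning("dichotomize: degenerate split, all values on one side")
    return labels


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    correction: str


def chi_square_2x2(table, correction: str = "none") -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2x2 table, df=1.

    ``correction="yates"`` subtracts 0.5 from each |O - E| before
    squaring. Zero row/column margins are an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if obs.min() < 0 or obs.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    if correction not in {"none", "yates"}:
        raise ValueError("correction must be 'none' or 'yates'")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=(correction == "yates"))
    return ChiSquareResult(float(stat), float(p), correction)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table with columns ``time`` and
    ``survival``; the curve starts at S(0)=1, drops only at event
    times, and stays flat when all subjects are censored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one subject required")
    if times.min() < 0:
        raise ValueError("negative follow-up time")
    km = KaplanMeierFitter()
    km.fit(times, events)
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank chi-square test (df=1)."""
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two non-empty groups required, got {levels}")
    g0 = df[df["group"] == levels[0]]
    g1 = df[df["group"] == levels[1]]
    res = _ll_logrank(g0["time"], g1["time"], g0["event"], g1["event"])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # univariate | multivariate


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    model: str = "univariate",
    select_p: float = 0.05,
) -> list[CoxResult]:
    """Cox proportional-hazards regression via partial likelihood
    (Efron ties), Wald confidence intervals and p-values.

    ``model="univariate"`` fits each covariate alone.
    ``model="multivariate"`` first runs the univariate screens and
    jointly fits the covariates with univariate p < ``select_p``.
    Constant covariates are reported as dropped rather than fitted.
    """
    if data[event_col].sum() < 1:
        raise ValueError("no events observed")
    results: list[CoxResult] = []

    def _fit(cols: list[str], tag: str) -> list[CoxResult]:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                data[[duration_col, event_col] + cols],
                duration_col=duration_col,
                event_col=event_col,
            )
        out = []
        summ = cph.summary
        for cov in cols:
            row = summ.loc[cov]
            out.append(
                CoxResult(
                    cov,
                    float(row["exp(coef)"]),
                    float(row["exp(coef) lower 95%"]),
                    float(row["exp(coef) upper 95%"]),
                    float(row["p"]),
                    tag,
                )
            )
        return out

    usable = []
    for cov in covariates:
        if data[cov].nunique() < 2:
            logger.warning("cox_fit: covariate %s is constant, skipped", cov)
            continue
        usable.append(cov)
    uni = []
    for cov in usable:
        uni.extend(_fit([cov], "univariate"))
    if model == "univariate":
        return uni
    if model != "multivariate":
        raise ValueError("model must be 'univariate' or 'multivariate'")
    carried = [r.covariate for r in uni if r.p_value < select_p]
    results = list(uni)
    if carried:
        results.extend(_fit(carried, "multivariate"))
    else:
        logger.warning("cox_fit: no covariate passed the univariate screen")
    return results


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: the Mann-Whitney probability that a
    positive outscores a negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def association_table(
    clinical: pd.DataFrame,
    marker_col: str,
    feature_cols: list[str],
    corrections: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Chi-squared association of a low/high marker with each binary
    clinical feature; one row per feature."""
    corrections = corrections or {}
    rows = []
    for feat in feature_cols:
        tab = pd.crosstab(clinical[feat], clinical[marker_col])
        if tab.shape != (2, 2):
            logger.warning("association_table: %s is not binary, skipped", feat)
            continue
        tab = tab.reindex(columns=[LOW, HIGH])
        corr = corrections.get(feat, "none")
        res = chi_square_2x2(tab.to_numpy(), correction=corr)
        rows.append(
            {
                "feature": feat,
                "n_low": int(tab[LOW].sum()),
                "n_high": int(tab[HIGH].sum()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "correction": corr,
            }
        )
    return pd.DataFrame(rows)
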