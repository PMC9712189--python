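"""Survival and response evaluation of fitted indices.

Kaplan-Meier curves and the log-rank test quantify the high/low risk-group
separation; Harrell's concordance index measures how well a continuous
score orders the observed survival; restricted mean survival time (the
area under the KM curve up to a truncation horizon, 120 months by default)
summarizes each group's life expectancy; a rank-based ROC/AUC measures how
well a score separates immunotherapy responders (CR/PR) from
non-responders (SD/PD).  The generic group-difference and correlation
statistics (Wilcoxon/Mann-Whitney, Kruskal-Wallis, Fisher's exact,
Spearman) used throughout the analysis are bundled in :func:`group_stats`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index, restricted_mean_survival_time
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datatypes import KMCurve, RiskAssignment
from .errors import DomainError, SchemaError, UndefinedTestError

RESPONDER_LEVELS = ("CR", "PR")
NONRESPONDER_LEVELS = ("SD", "PD")


def dichotomize_response(response4: pd.Series) -> pd.Series:
    """Collapse CR/PR/SD/PD to responder (1 = CR/PR) vs non-responder (0)."""
    known = set(RESPONDER_LEVELS) | set(NONRESPONDER_LEVELS)
    values = response4.dropna()
    bad = sorted(set(values.unique()) - known)
    if bad:
        raise SchemaError(f"unknown response labels: {bad}")
    out = values.isin(RESPONDER_LEVELS).astype(int)
    return out.reindex(response4.index)


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate with right censoring."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise DomainError("cannot estimate a survival curve from zero subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    times = np.r_[0.0, observed.index.to_numpy(float)]
    surv = np.r_[1.0, kmf.survival_function_.loc[observed.index, "KM_estimate"].to_numpy(float)]
    n_at_risk = np.r_[len(time), observed["at_risk"].to_numpy(float)]
    return KMCurve(times=times, survival=surv, n_at_risk=n_at_risk)


def harrell_cindex(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of a *risk* score (higher = earlier death).

    Pairs are comparable iff the shorter observed time is an event; score
    ties contribute 0.5.  Perfect risk ordering gives 1.0.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() == 0:
        raise UndefinedTestError("concordance undefined without any events")
    try:
        # lifelines scores concordance of a *survival* prediction, so negate.
        return float(concordance_index(time, -scores, event_observed=event))
    except ZeroDivisionError as exc:
        raise UndefinedTestError("no comparable pairs for the concordance index") from exc


def rms_time(time: np.ndarray, event: np.ndarray, tau: float) -> float:
    """Restricted mean survival time: area under the KM curve on [0, tau]."""
    if tau <= 0:
        raise DomainError("tau must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), event_observed=np.asarray(event, int))
    return float(restricted_mean_survival_time(kmf, t=tau))


def rms_ratio_by_group(
    risk: RiskAssignment, time: pd.Series, event: pd.Series, tau: float
) -> float:
    """Ratio of low-group to high-group restricted mean survival at ``tau``.

    Values above 1 mean the low-risk group lives longer within the horizon.
    """
    lo, hi = risk.low_ids, risk.high_ids
    if len(lo) == 0 or len(hi) == 0:
        raise DomainError("both risk groups must be non-empty for the RMS ratio")
    rms_lo = rms_time(time.loc[lo].to_numpy(), event.loc[lo].to_numpy(), tau)
    rms_hi = rms_time(time.loc[hi].to_numpy(), event.loc[hi].to_numpy(), tau)
    return float(rms_lo / rms_hi)


def binary_roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n1*n0)); score ties contribute 0.5."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) != 2:
        raise DomainError("AUC needs both label classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def group_stats(data, test: str) -> tuple[float, float]:
    """Classical two-or-more-group / association statistics.

    ``test`` selects:

    * ``"wilcoxon"`` — two-sided Mann-Whitney U on two groups;
    * ``"kruskal"`` — Kruskal-Wallis across >= 2 groups;
    * ``"fisher"`` — Fisher's exact test on a contingency table;
    * ``"spearman"`` — Spearman correlation of two paired vectors.

    Returns (statistic, p-value).
    """
    if test == "wilcoxon":
        if len(data) != 2:
            raise DomainError("wilcoxon expects exactly two groups")
        res = stats.mannwhitneyu(np.asarray(data[0], float), np.asarray(data[1], float))
    elif test == "kruskal":
        if len(data) < 2:
            raise DomainError("kruskal expects at least two groups")
        res = stats.kruskal(*[np.asarray(g, float) for g in data])
    elif test == "fisher":
        table = np.asarray(data)
        if table.ndim != 2 or min(table.shape) < 2:
            raise DomainError("fisher expects a 2x2 or r x c contingency table")
        res = stats.fisher_exact(table)
    elif test == "spearman":
        if len(data) != 2 or len(data[0]) != len(data[1]):
            raise DomainError("spearman expects two paired vectors")
        res = stats.spearmanr(np.asarray(data[0], float), np.asarray(data[1], float))
    else:
        raise DomainError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def cyt_score(expr: pd.DataFrame | pd.Series, genes: tuple[str, str] = ("PRF1", "GZMA")):
    """Cytolytic activity: mean expression of PRF1 and GZMA.

    Accepts one sample (Series indexed by gene) or a gene x sample matrix;
    returns a float or a per-sample Series accordingly.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise SchemaError(f"cytolytic-score genes missing from expression: {missing}")
    if isinstance(expr, pd.Series):
        return float(np.mean([expr[g] for g in genes]))
    return expr.loc[list(genes)].mean(axis=0)


def cindex_difference_bootstrap(
    scores_a: pd.Series,
    scores_b: pd.Series,
    time: pd.Series,
    event: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired bootstrap test for the difference of two scores' C-indices.

    Resamples subjects with replacement, recomputes both concordance
    indices on each replicate, and returns (observed difference a - b,
    two-sided bootstrap p-value for difference = 0).
    """
    common = scores_a.index.intersection(scores_b.index)
    t = time.loc[common].to_numpy(float)
    e = event.loc[common].to_numpy(int)
    a = scores_a.loc[common].to_numpy(float)
    b = scores_b.loc[common].to_numpy(float)
    observed = harrell_cindex(a, t, e) - harrell_cindex(b, t, e)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n = len(common)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            diffs[i] = harrell_cindex(a[idx], t[idx], e[idx]) - harrell_cindex(
                b[idx], t[idx], e[idx]
            )
        except UndefinedTestError:
            diffs[i] = np.nan
    diffs = diffs[np.isfinite(diffs)]
    centered = diffs - diffs.mean()
    p = float((np.abs(centered) >= abs(observed)).mean())
    return float(observed), p
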