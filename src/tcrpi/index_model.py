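"""Fitting the pair-based prognostic index and the composite clinical index.

The training protocol is fixed:

1. the pooled meta-cohort is split at random into four equal parts
   (training, test 1-3);
2. pairs whose 0/1 split of the *training* samples separates survival at
   log-rank p < 0.05 enter a LASSO-penalized Cox regression;
3. the penalty is chosen by cross-validated partial-likelihood deviance;
4. the LASSO support is refit by unpenalized multivariate Cox and features
   retained at Wald p < 0.05; their coefficients define the index
   ``TCRPI(s) = sum_i coef_i * pair_i(s)``;
5. a time-dependent ROC of the training index at the 5-year horizon yields
   the risk cutoff (the threshold closest to the ideal corner), which is
   then applied unchanged to every test part.

Only the training quarter ever touches survival before the model is
frozen; the test parts are used solely for evaluation.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import CompositeIndexModel, PairIndexModel, RiskAssignment, ROCCurve
from .errors import (
    ConvergenceError,
    DomainError,
    SchemaError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort splitting


def split_cohort(
    sample_ids: Sequence[str], seed: int, n_parts: int = 4
) -> list[list[str]]:
    """Random partition of the pooled samples into ``n_parts`` equal parts.

    Part sizes differ by at most one (the leading parts take the
    remainder); the partition is a deterministic function of ``seed``.
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate sample ids in split")
    if len(ids) < n_parts:
        raise DomainError(f"need at least {n_parts} samples to split, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    base, extra = divmod(len(ids), n_parts)
    parts: list[list[str]] = []
    start = 0
    for k in range(n_parts):
        size = base + (1 if k < extra else 0)
        parts.append([ids[i] for i in perm[start : start + size]])
        start += size
    return parts


# ---------------------------------------------------------------------------
# Log-rank screening


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, int), np.asarray(event_b, int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise UndefinedTestError("log-rank test needs two non-empty groups")
    if event_a.sum() + event_b.sum() == 0:
        raise UndefinedTestError("log-rank test undefined without any events")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def select_prognostic_pairs(
    pm: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
) -> list[str]:
    """Pairs whose 0-vs-1 training split separates survival at log-rank p < alpha.

    ``pm`` must be restricted to the training samples; pairs with an empty
    group on the training set are skipped with a warning.
    """
    time = time.loc[pm.columns]
    event = event.loc[pm.columns]
    t = time.to_numpy(float)
    e = event.to_numpy(int)
    selected: list[str] = []
    for pair, row in pm.iterrows():
        mask = row.to_numpy() == 1
        if mask.all() or (~mask).all():
            logger.warning("pair %s has one empty group on the training set; skipped", pair)
            continue
        try:
            _, p = logrank_test(t[mask], e[mask], t[~mask], e[~mask])
        except UndefinedTestError:
            logger.warning("pair %s: log-rank undefined on the training set; skipped", pair)
            continue
        if p < alpha:
            selected.append(str(pair))
    return selected


# ---------------------------------------------------------------------------
# Penalized and unpenalized Cox fitting


def cox_partial_loglik(
    X: np.ndarray, beta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of a Cox model at fixed coefficients."""
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="mergesort")
    eta_o, time_o, event_o = eta[order], time[order], event[order]
    lse = np.logaddexp.accumulate(eta_o)
    n = len(eta_o)
    change = np.r_[True, time_o[1:] != time_o[:-1]]
    gid = np.cumsum(change) - 1
    starts = np.nonzero(change)[0]
    group_last = np.r_[starts[1:] - 1, n - 1]
    denom = lse[group_last[gid]]
    return float(np.sum((eta_o - denom)[event_o == 1]))


def _coxnet_coefs(X: np.ndarray, y, alphas: np.ndarray) -> np.ndarray:
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coefs = np.zeros((X.shape[1], len(alphas)))
    fitted = np.asarray(model.alphas_)
    # Coxnet may truncate a path it cannot complete; align by alpha value.
    for j, a in enumerate(alphas):
        k = int(np.argmin(np.abs(fitted - a)))
        coefs[:, j] = model.coef_[:, k]
    return coefs


def fit_lasso_cox(
    X: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    penalty: float | None = None,
) -> tuple[pd.Series, dict]:
    """L1-penalized Cox regression with cross-validated penalty choice.

    ``X`` is samples x features (binary pair features in the pipeline).
    The penalty path is generated on the full training data and the held-out
    partial-likelihood deviance is accumulated over ``folds`` seeded folds;
    ``lambda_rule`` picks either the deviance minimizer (``"min"``) or the
    1-standard-error rule (``"1se"``).  Passing ``penalty`` overrides the
    search; ``penalty=0`` fits the unpenalized model.

    Returns the full coefficient vector (zeros included) and a metadata
    dict with the chosen penalty.
    """
    time = time.loc[X.index]
    event = event.loc[X.index]
    t = time.to_numpy(float)
    e = event.to_numpy(int)
    if e.sum() == 0:
        raise DomainError("cannot fit a Cox model without any events")
    if lambda_rule not in ("min", "1se"):
        raise DomainError(f"unknown lambda rule {lambda_rule!r}")
    Xv = X.to_numpy(float)
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    if penalty is not None:
        if penalty < 0:
            raise DomainError("penalty must be non-negative")
        if penalty == 0:
            coef = _unpenalized_cox(X, time, event)
            return coef.reindex(X.columns).fillna(0.0), {"penalty": 0.0, "rule": "fixed"}
        coefs = _coxnet_coefs(Xv, y, np.array([penalty]))
        series = pd.Series(coefs[:, 0], index=X.columns)
        if (series == 0).all():
            logger.warning("all coefficients are zero at the requested penalty %g", penalty)
        return series, {"penalty": float(penalty), "rule": "fixed"}

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=50, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xv, y)
    alphas = np.asarray(path.alphas_)

    if e.sum() < folds:
        raise DomainError(f"need at least {folds} events for {folds}-fold cross-validation")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(alphas)))
    for k, (tr, te) in enumerate(kf.split(Xv)):
        if e[tr].sum() == 0 or e[te].sum() == 0:
            continue
        fold_coefs = _coxnet_coefs(Xv[tr], y[tr], alphas)
        for j in range(len(alphas)):
            dev[k, j] = -2.0 * cox_partial_loglik(Xv[te], fold_coefs[:, j], t[te], e[te])
    total = dev.sum(axis=0)
    j_min = int(np.argmin(total))
    if lambda_rule == "1se":
        se = dev.std(axis=0, ddof=1) * np.sqrt(folds)
        limit = total[j_min] + se[j_min]
        eligible = np.nonzero(total <= limit)[0]
        j_star = int(eligible[np.argmax(alphas[eligible])])
    else:
        j_star = j_min
    coef = pd.Series(_coxnet_coefs(Xv, y, alphas)[:, j_star], index=X.columns)
    if (coef == 0).all():
        logger.warning("LASSO selected the empty model at the chosen penalty")
    meta = {"penalty": float(alphas[j_star]), "rule": lambda_rule, "folds": folds, "seed": seed}
    return coef, meta


def _unpenalized_cox(X: pd.DataFrame, time: pd.Series, event: pd.Series) -> pd.Series:
    df = X.astype(float).copy()
    df["__time"] = time.loc[X.index].to_numpy(float)
    df["__event"] = event.loc[X.index].to_numpy(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="__time",
                event_col="__event",
                fit_options={"precision": 1e-09, "max_steps": 500},
            )
    except Exception as exc:  # lifelines raises its own ConvergenceError
        raise ConvergenceError(f"unpenalized Cox fit failed: {exc}") from exc
    return cph.params_


def _cox_summary(X: pd.DataFrame, time: pd.Series, event: pd.Series) -> pd.DataFrame:
    df = X.astype(float).copy()
    df["__time"] = time.loc[X.index].to_numpy(float)
    df["__event"] = event.loc[X.index].to_numpy(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="__time",
                event_col="__event",
                fit_options={"precision": 1e-09, "max_steps": 500},
            )
    except Exception as exc:
        raise ConvergenceError(f"multivariate Cox fit failed: {exc}") from exc
    return cph.summary[["coef", "p"]]


def fit_final_cox(
    X: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    p_threshold: float = 0.05,
    retention: str = "wald",
) -> pd.Series:
    """Unpenalized multivariate Cox on the LASSO support, with Wald retention.

    Features with multivariate Wald p below ``p_threshold`` are kept and the
    model refit on them; their refit coefficients are the index weights.
    ``retention="keep_all"`` skips the pruning.  Returns an empty series
    (with a warning) if nothing survives.
    """
    if retention not in ("wald", "keep_all"):
        raise DomainError(f"unknown retention rule {retention!r}")
    summary = _cox_summary(X, time, event)
    if retention == "keep_all":
        return summary["coef"]
    kept = summary.index[summary["p"] < p_threshold].tolist()
    if not kept:
        logger.warning("no feature met Wald p < %g; the index is empty", p_threshold)
        return pd.Series(dtype=float)
    if len(kept) == X.shape[1]:
        return summary["coef"]
    return _cox_summary(X[kept], time, event)["coef"]


# ---------------------------------------------------------------------------
# Index scoring, ROC cutoff, risk groups


def compute_tcrpi(pm: pd.DataFrame, model: PairIndexModel | Mapping[str, float]) -> pd.Series:
    """Weighted sum of pair features: ``score(s) = sum_i coef_i * pair_i(s)``."""
    coefs = model.coefficients if isinstance(model, PairIndexModel) else dict(model)
    missing = [p for p in coefs if p not in pm.index]
    if missing:
        raise SchemaError(f"pair matrix is missing model pairs: {missing}")
    scores = pd.Series(0.0, index=pm.columns, name="tcrpi")
    for pair, coef in coefs.items():
        scores = scores + float(coef) * pm.loc[pair].astype(float)
    scores.name = "tcrpi"
    return scores


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit survival estimate S(t) (vectorized; 1.0 for empty input)."""
    if len(time) == 0:
        return 1.0
    order = np.argsort(time, kind="mergesort")
    ts, es = time[order], event[order]
    uniq, start = np.unique(ts, return_index=True)
    deaths = np.add.reduceat(es, start)
    n_at_risk = len(ts) - start
    mask = (uniq <= t) & (deaths > 0)
    return float(np.prod(1.0 - deaths[mask] / n_at_risk[mask]))


def time_dependent_roc(
    scores: pd.Series | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t_star: float,
) -> ROCCurve:
    """Cumulative-case/dynamic-control ROC at horizon ``t_star``.

    Cases are subjects with T <= t_star, controls those with T > t_star;
    censoring is handled with Kaplan-Meier survival estimates (the
    Heagerty-Lumley-Pepe construction):

        sens(c) = P(score > c) * (1 - S_{>c}(t*)) / (1 - S(t*))
        spec(c) = P(score <= c) * S_{<=c}(t*) / S(t*)

    Thresholds sweep the observed score values; the AUC is trapezoidal over
    the resulting (1 - spec, sens) points.  Without censoring this reduces
    exactly to the binary ROC with label (T <= t_star).
    """
    s = np.asarray(scores.to_numpy() if isinstance(scores, pd.Series) else scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not ((time <= t_star) & (event == 1)).any():
        raise DomainError(f"no observed events before t*={t_star}")
    if not (time > t_star).any():
        raise DomainError(f"no subjects at risk beyond t*={t_star}")
    s_overall = _km_survival_at(time, event, t_star)
    if s_overall in (0.0, 1.0):
        raise DomainError("degenerate overall survival at the ROC horizon")
    n = len(s)
    rows = []
    for c in np.unique(s):
        hi = s > c
        p_hi = hi.mean()
        s_hi = _km_survival_at(time[hi], event[hi], t_star)
        s_lo = _km_survival_at(time[~hi], event[~hi], t_star)
        sens = p_hi * (1.0 - s_hi) / (1.0 - s_overall)
        spec = (1.0 - p_hi) * s_lo / s_overall
        rows.append((float(c), float(np.clip(sens, 0, 1)), float(np.clip(spec, 0, 1))))
    points = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    # integrate along the parametric path (thresholds decreasing), which runs
    # from (0, 0) to (1, 1) in (1 - specificity, sensitivity) space
    fpr = np.r_[0.0, 1.0 - points["specificity"].to_numpy()[::-1], 1.0]
    tpr = np.r_[0.0, points["sensitivity"].to_numpy()[::-1], 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=points, auc=auc, horizon=float(t_star))


def select_cutoff(roc: ROCCurve) -> float:
    """Threshold minimizing the distance to the ideal corner (0, 1).

    Distance is Euclidean in (1 - specificity, sensitivity) space; ties go
    to the smaller threshold.
    """
    pts = roc.points
    if len(pts) == 0:
        raise DomainError("empty ROC curve")
    ordered = pts.sort_values("threshold")
    d = np.sqrt(
        (1.0 - ordered["sensitivity"]) ** 2 + (1.0 - ordered["specificity"]) ** 2
    ).to_numpy()
    return float(ordered["threshold"].to_numpy()[int(np.argmin(d))])


def assign_risk(scores: pd.Series, cutoff: float) -> RiskAssignment:
    """High-risk iff score strictly exceeds the cutoff (ties fall to low)."""
    if not np.isfinite(cutoff):
        raise DomainError("cutoff must be finite")
    group = pd.Series(
        np.where(scores.to_numpy(float) > cutoff, "high", "low"),
        index=scores.index,
        name="group",
    )
    return RiskAssignment(scores=scores.astype(float), group=group, cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# Composite clinical index

DEFAULT_ENCODINGS: dict[str, dict] = {
    "age": {"kind": "threshold", "cutoff": 65.0},
    "gender": {"kind": "indicator", "positive": "male"},
    "stage": {"kind": "binary", "high": ["III", "IV"]},
    "grade": {"kind": "indicator", "positive": "high"},
    "tcrpi": {"kind": "continuous"},
}


def encode_clinical(
    clinical: pd.DataFrame,
    tcrpi: RiskAssignment | pd.Series,
    encodings: Mapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Numeric feature matrix for the composite index.

    Default encodings: age dichotomized at >65 years, gender male=1,
    stage collapsed to III-IV=1, grade high=1, and the pair index entered
    as its continuous score (a ``{"kind": "group"}`` risk-indicator
    alternative is available; the continuous default keeps the composite
    at least as informative as the index alone).  ``{"kind":
    "continuous"}`` likewise switches age or stage (ordinal I..IV -> 1..4)
    to continuous form.  Samples with missing values in any encoded column
    are dropped.
    """
    enc = {**DEFAULT_ENCODINGS, **(dict(encodings) if encodings else {})}
    out = pd.DataFrame(index=clinical.index)

    def _cont_stage(s: pd.Series) -> pd.Series:
        return s.map({"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0})

    def _indicator(raw: pd.Series, flag: pd.Series) -> pd.Series:
        # keep missing values missing so incomplete cases are dropped, not zeroed
        return flag.astype(float).mask(raw.isna())

    for name, spec in enc.items():
        kind = spec.get("kind")
        if name == "age":
            col = clinical["age_years"].astype(float)
            out[name] = col if kind == "continuous" else _indicator(col, col > float(spec["cutoff"]))
        elif name == "gender":
            col = clinical["gender"]
            out[name] = _indicator(col, col == spec.get("positive", "male"))
        elif name == "stage":
            if kind == "continuous":
                out[name] = _cont_stage(clinical["stage"])
            else:
                col = clinical["stage"]
                out[name] = _indicator(col, col.isin(spec.get("high", ["III", "IV"])))
        elif name == "grade":
            col = clinical["grade"]
            out[name] = _indicator(col, col == spec.get("positive", "high"))
        elif name == "tcrpi":
            if isinstance(tcrpi, RiskAssignment):
                values = (
                    tcrpi.scores
                    if kind == "continuous"
                    else (tcrpi.group == "high").astype(float)
                )
            else:
                values = pd.Series(tcrpi, copy=False).astype(float)
            out[name] = values.reindex(clinical.index)
        else:
            raise SchemaError(f"unknown composite feature {name!r}")
    return out.dropna()


def fit_ctcpi(
    tcrpi: RiskAssignment | pd.Series,
    clinical: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    encodings: Mapping[str, dict] | None = None,
    p_threshold: float = 0.05,
) -> CompositeIndexModel:
    """Composite clinical + pair-index model by multivariable Cox retention.

    All candidate features (age, gender, stage, grade, pair index) enter a
    multivariable Cox model on complete cases; features at Wald p below
    ``p_threshold`` are retained and refit, and their coefficients define
    the composite score.  If nothing is retained the model degrades (with a
    warning) to the pair index alone.
    """
    enc = {**DEFAULT_ENCODINGS, **(dict(encodings) if encodings else {})}
    features = encode_clinical(clinical, tcrpi, enc)
    if features.empty:
        raise DomainError("no complete cases for the composite index")
    t = time.reindex(features.index)
    e = event.reindex(features.index)
    keep_rows = t.notna() & e.notna()
    features, t, e = features.loc[keep_rows], t.loc[keep_rows], e.loc[keep_rows]
    # Constant columns carry no information and break the fit.
    informative = features.columns[features.nunique() > 1]
    dropped_constant = [c for c in features.columns if c not in informative]
    if dropped_constant:
        logger.warning("constant composite features dropped: %s", dropped_constant)
    summary = _cox_summary(features[list(informative)], t, e)
    kept = summary.index[summary["p"] < p_threshold].tolist()
    if not kept:
        logger.warning("no composite feature met Wald p < %g; using the pair index alone", p_threshold)
        kept = ["tcrpi"]
    if set(kept) != set(summary.index):
        summary = _cox_summary(features[kept], t, e)
    order = [n for n in ("age", "stage", "tcrpi", "gender", "grade") if n in kept]
    terms = [(n, float(summary.loc[n, "coef"])) for n in order]
    return CompositeIndexModel(terms=terms, encodings={k: enc[k] for k in order})
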