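"""Independent brute-force oracles used to cross-check the implementation.

Every function here re-derives a statistic from first principles (explicit
loops, enumeration, root-finding), deliberately sharing no code with the
package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def ssgsea_bruteforce(expr: dict[str, float], gene_set: set[str], alpha: float) -> float:
    """Step-by-step running-sum enrichment score for one sample."""
    genes = list(expr)
    values = [expr[g] for g in genes]
    n = len(genes)
    # average ranks, ascending: highest expression gets rank n
    ranks = {}
    for i, g in enumerate(genes):
        less = sum(1 for v in values if v < values[i])
        equal = sum(1 for v in values if v == values[i])
        ranks[g] = less + (equal + 1) / 2.0
    order = sorted(range(n), key=lambda i: (-values[i], i))  # decreasing expression
    in_set = [genes[i] in gene_set for i in order]
    weights = [abs(ranks[genes[i]]) ** alpha if genes[i] in gene_set else 0.0 for i in order]
    total_w = sum(weights)
    n_out = n - sum(in_set)
    score = 0.0
    cum_w = 0.0
    cum_out = 0
    for i in range(n):
        cum_w += weights[i]
        cum_out += 0 if in_set[i] else 1
        score += cum_w / total_w - cum_out / n_out
    return score


def logrank_enumeration(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square by explicit risk-set enumeration."""
    from scipy.stats import chi2

    records = [(t, e, 0) for t, e in zip(time_a, event_a)] + [
        (t, e, 1) for t, e in zip(time_b, event_b)
    ]
    event_times = sorted({t for t, e, _ in records if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in records if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, 1))


def km_survival_steps(time, event) -> list[tuple[float, float]]:
    """Hand product-limit estimate: list of (event time, survival just after)."""
    records = sorted(zip(time, event))
    out = []
    surv = 1.0
    n = len(records)
    event_times = sorted({t for t, e in records if e == 1})
    for t in event_times:
        at_risk = sum(1 for tt, _ in records if tt >= t)
        deaths = sum(1 for tt, ee in records if tt == t and ee == 1)
        surv *= 1.0 - deaths / at_risk
        out.append((t, surv))
    return out


def rms_integration(time, event, tau: float) -> float:
    """Exact step integration of the hand product-limit curve on [0, tau]."""
    steps = km_survival_steps(time, event)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in steps:
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * (tau - prev_t)
    return area


def cindex_enumeration(scores, time, event) -> float:
    """Harrell's C by explicit enumeration of all comparable pairs."""
    n = len(scores)
    num = 0.0
    den = 0
    for i, j in combinations(range(n), 2):
        # order so that i has the shorter observed time
        if time[j] < time[i]:
            i, j = j, i
        if time[i] == time[j]:
            if event[i] == 1 and event[j] == 1:
                continue  # tied event times: not comparable
            if event[i] == event[j] == 0:
                continue
            if event[j] == 1:  # make i the event
                i, j = j, i
        if event[i] != 1:
            continue  # shorter time censored: not comparable
        den += 1
        if scores[i] > scores[j]:
            num += 1.0
        elif scores[i] == scores[j]:
            num += 0.5
    return num / den


def auc_u_statistic(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            u += 1.0 if p > q else (0.5 if p == q else 0.0)
    return u / (len(pos) * len(neg))


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def hyper(k: int) -> float:
        return (
            math.comb(col1, k) * math.comb(n - col1, row1 - k) / math.comb(n, row1)
        )

    p_obs = hyper(a)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    return sum(hyper(k) for k in range(lo, hi + 1) if hyper(k) <= p_obs * (1 + 1e-12))


def cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray, iters: int = 50) -> np.ndarray:
    """Unpenalized Cox fit by Newton iteration on the partial likelihood (no ties)."""
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(time)
    Xs, ts, es = X[order], time[order], event[order]
    for _ in range(iters):
        eta = Xs @ beta
        w = np.exp(eta)
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for i in range(n):
            if es[i] != 1:
                continue
            risk = np.arange(n) >= i  # sorted ascending, no ties
            denom = w[risk].sum()
            xbar = (w[risk, None] * Xs[risk]).sum(axis=0) / denom
            grad += Xs[i] - xbar
            xc = Xs[risk] - xbar
            hess += (w[risk, None, None] * (xc[:, :, None] * xc[:, None, :])).sum(axis=0) / denom
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def univariate_cox_bisection(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Single-covariate Cox coefficient by bisection on the score equation."""

    def score(beta: float) -> float:
        order = np.argsort(time)
        xs, ts, es = x[order], time[order], event[order]
        w = np.exp(beta * xs)
        total = 0.0
        for i in range(len(xs)):
            if es[i] != 1:
                continue
            risk = np.arange(len(xs)) >= i
            total += xs[i] - (w[risk] * xs[risk]).sum() / w[risk].sum()
        return total

    lo, hi = -10.0, 10.0
    assert score(lo) * score(hi) < 0, "score equation not bracketed"
    for _ in range(200):
        mid = (lo + hi) / 2
        if score(lo) * score(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2
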