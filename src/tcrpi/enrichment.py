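"""Single-sample gene-set enrichment (ssGSEA) scoring.

Each sample is scored against each cell-type gene set with the
single-sample running-sum statistic of Barbie et al.: genes are ranked by
expression within the sample (average ranks for ties, the top gene holding
the largest rank), and the score is the sum over the ranked list of the
difference between the weighted in-set empirical CDF — weights
``|rank|**alpha`` — and the unweighted out-of-set empirical CDF.  Because
the statistic depends on the expression vector only through its
within-sample ranks, any strictly increasing transform of a sample leaves
all of its scores unchanged; this is the property the downstream pair
features rely on.

Scores are normalized by dividing the whole cell-type x sample matrix by
its global range (max - min), so the matrix spans exactly one unit.  The
normalization rescales every sample by the same positive constant and
therefore cannot change any within-sample comparison.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort
from .errors import DegenerateInputError, DomainError

logger = logging.getLogger(__name__)

#: Default exponent of the rank weights; the established ssGSEA default.
DEFAULT_ALPHA = 0.25


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, ascending (highest expression -> rank n)."""
    df = pd.DataFrame(values)
    return df.rank(axis=0, method="average").to_numpy()


def _resolve_set(gene_set: Sequence[str], universe: pd.Index, name: str = "") -> np.ndarray:
    members = pd.Index(pd.unique(pd.Series(list(gene_set))))
    if len(members) == 0:
        raise DomainError(f"gene set {name!r} is empty")
    present = members.intersection(universe)
    dropped = len(members) - len(present)
    if dropped:
        logger.warning("gene set %r: %d gene(s) absent from the matrix were dropped", name, dropped)
    if len(present) == 0:
        raise DomainError(f"gene set {name!r} has no genes in the expression universe")
    if len(present) == len(universe):
        raise DomainError(f"gene set {name!r} equals the whole gene universe")
    return universe.isin(present)


def _running_sum_scores(
    ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized running-sum statistic for one set over all samples.

    ``ranks`` is genes x samples, ``order`` the per-column gene ordering by
    decreasing rank, ``in_set`` a boolean gene vector.
    """
    n_genes, _ = ranks.shape
    in_ord = in_set[order]
    ranks_ord = np.take_along_axis(ranks, order, axis=0)
    weights = np.where(in_ord, np.abs(ranks_ord) ** alpha, 0.0)
    p_in = np.cumsum(weights, axis=0) / weights.sum(axis=0)
    n_out = n_genes - int(in_set.sum())
    p_out = np.cumsum(~in_ord, axis=0) / n_out
    return (p_in - p_out).sum(axis=0)


def _decreasing_order(ranks: np.ndarray) -> np.ndarray:
    """Per-column order of genes by decreasing rank, ties broken by gene position."""
    n_genes, n_samples = ranks.shape
    idx = np.broadcast_to(np.arange(n_genes)[:, None], (n_genes, n_samples))
    return np.lexsort((idx, -ranks), axis=0)


def ssgsea_sample_score(
    expr_one_sample: Mapping[str, float] | pd.Series,
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Running-sum enrichment score of one gene set in one sample.

    ``expr_one_sample`` maps gene ids to expression values; ``gene_set``
    must be a non-empty strict subset of that universe (unknown ids are
    dropped with a warning).  ``alpha >= 0`` is the rank-weight exponent.
    """
    if alpha < 0:
        raise DomainError(f"alpha must be non-negative, got {alpha}")
    series = pd.Series(dict(expr_one_sample)) if not isinstance(expr_one_sample, pd.Series) else expr_one_sample
    values = series.to_numpy(dtype=float)[:, None]
    if not np.isfinite(values).all():
        raise DomainError("non-finite expression values")
    in_set = _resolve_set(gene_set, series.index)
    ranks = _rank_matrix(values)
    order = _decreasing_order(ranks)
    return float(_running_sum_scores(ranks, order, in_set, alpha)[0])


def ssgsea_matrix(
    cohort: ExpressionCohort | pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Raw (unnormalized) cell-type x sample enrichment score matrix.

    Each column is scored independently; the sample order of the cohort is
    preserved.  The per-column ordering work is shared across sets, so
    scoring 19 sets costs one sort per sample plus 19 cheap passes.
    """
    if alpha < 0:
        raise DomainError(f"alpha must be non-negative, got {alpha}")
    expr = cohort.values if isinstance(cohort, ExpressionCohort) else cohort
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("non-finite expression values")
    ranks = _rank_matrix(values)
    order = _decreasing_order(ranks)
    rows = {}
    for name, members in sets.items():
        in_set = _resolve_set(members, expr.index, name)
        rows[name] = _running_sum_scores(ranks, order, in_set, alpha)
    return pd.DataFrame(rows, index=expr.columns).T


def normalize_enrichment(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide the whole score matrix by its global range (max - min).

    The normalized matrix spans exactly one unit.  Rescaling by a single
    positive constant preserves every within-sample ordering, so downstream
    pair features are identical whether built from raw or normalized scores.
    """
    values = raw.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("non-finite enrichment scores")
    span = values.max() - values.min()
    if span <= 0:
        raise DegenerateInputError("constant enrichment matrix cannot be normalized")
    return raw / span
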