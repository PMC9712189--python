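"""Binary cell-pair features from enrichment scores.

The pair transform is the heart of the cross-platform strategy: instead of
the (platform-dependent) enrichment values themselves, each sample is
described by the within-sample *ordering* of its cell-type scores.  For an
unordered cell-type pair {a, b} (stored canonically with a before b), the
pair feature is 1 when type a's score strictly exceeds type b's and 0
otherwise.  Because the feature only compares two numbers measured in the
same sample, any strictly increasing per-sample transformation of the
expression data — and hence of the enrichment scores — leaves the whole
feature matrix unchanged, which is what lets cohorts from different
platforms be pooled without explicit batch correction.

Pairs that are constant (all 0 or all 1) across the pooled analysis set
carry no information and are dropped before modelling.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import pair_label
from .errors import DomainError

logger = logging.getLogger(__name__)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair {a, b} in canonical (lexicographic) order."""
    if a == b:
        raise DomainError(f"a pair needs two distinct cell types, got {a!r} twice")
    return (a, b) if a < b else (b, a)


def enumerate_pairs(cell_types: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of ``cell_types``, each in canonical order.

    For k cell types the result has k*(k-1)/2 entries (19 types -> 171
    pairs).  Raises :class:`DomainError` on duplicate names.
    """
    names = list(cell_types)
    if len(set(names)) != len(names):
        raise DomainError("duplicate cell-type names in pair enumeration")
    if len(names) < 2:
        raise DomainError("need at least 2 cell types to form pairs")
    return [canonical_pair(a, b) for a, b in combinations(names, 2)]


def pair_score(nes_a: float, nes_b: float) -> int:
    """1 iff ``nes_a`` strictly exceeds ``nes_b``, else 0 (ties score 0)."""
    if not (np.isfinite(nes_a) and np.isfinite(nes_b)):
        raise DomainError("pair_score requires finite enrichment scores")
    return int(nes_a > nes_b)


def build_pair_matrix(nes: pd.DataFrame) -> pd.DataFrame:
    """Binary pair x sample matrix from a cell-type x sample score matrix.

    Row ``"a|b"`` holds ``1`` for samples where type a's score strictly
    exceeds type b's.  The row order follows :func:`enumerate_pairs` on the
    matrix's cell-type order.
    """
    values = nes.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("non-finite enrichment scores")
    pairs = enumerate_pairs(list(nes.index))
    pos = {name: i for i, name in enumerate(nes.index)}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])
    scores = (values[ia] > values[ib]).astype(np.int8)
    return pd.DataFrame(scores, index=[pair_label(p) for p in pairs], columns=nes.columns)


def filter_constant_pairs(
    pm: pd.DataFrame, frequency_band: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Drop pairs whose feature is constant over all samples.

    A pair is kept iff its row contains both a 0 and a 1.  Optionally a
    frequency band (lo, hi) restricts further to pairs whose 1-frequency
    lies inside [lo, hi]; the default keeps the strict constant-only rule.
    Row order is preserved.  An empty result is a warning, not an error.
    """
    freq = pm.mean(axis=1)
    keep = (freq > 0) & (freq < 1)
    if frequency_band is not None:
        lo, hi = frequency_band
        if not (0 <= lo < hi <= 1):
            raise DomainError(f"invalid frequency band ({lo}, {hi})")
        keep &= (freq >= lo) & (freq <= hi)
    out = pm.loc[keep]
    if out.shape[0] == 0:
        logger.warning("all %d pairs were filtered out as constant", pm.shape[0])
    return out
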