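"""Core containers shared across the pipeline.

Matrices are held as :class:`pandas.DataFrame` throughout — genes x samples
for expression, cell types x samples for enrichment scores, pairs x samples
for the binary pair features — with identifiers on the index/columns.  The
dataclasses below wrap the objects that carry extra structure (a fitted
index, a risk assignment, a ROC curve) and handle JSON round-tripping of the
fitted models so a model trained on one study can be re-applied verbatim to
new cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

#: Minimum cohort size admitted to an analysis (small series carry too little
#: survival information to contribute to a meta-cohort).
MIN_COHORT_SAMPLES = 20

PAIR_SEP = "|"


@dataclass
class ExpressionCohort:
    """A gene x sample log-scale expression matrix for one platform/cohort.

    Parameters
    ----------
    values:
        DataFrame with gene identifiers on the index and sample identifiers
        on the columns.  Values must be finite; identifiers must be unique.
    cohort_id:
        Label for the cohort (used in provenance and error messages).
    """

    values: pd.DataFrame
    cohort_id: str

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise SchemaError(f"duplicated gene id {dup!r} in cohort {self.cohort_id!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise SchemaError(f"duplicated sample id {dup!r} in cohort {self.cohort_id!r}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise DomainError(f"non-finite expression values in cohort {self.cohort_id!r}")
        if v.shape[1] < MIN_COHORT_SAMPLES:
            raise DomainError(
                f"cohort {self.cohort_id!r} has {v.shape[1]} samples; "
                f"at least {MIN_COHORT_SAMPLES} are required"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def pair_label(pair: tuple[str, str]) -> str:
    """Serialize an (a, b) cell-type pair as ``"a|b"``."""
    return f"{pair[0]}{PAIR_SEP}{pair[1]}"


def parse_pair_label(label: str) -> tuple[str, str]:
    parts = label.split(PAIR_SEP)
    if len(parts) != 2:
        raise SchemaError(f"malformed pair label {label!r}")
    return parts[0], parts[1]


@dataclass
class ROCCurve:
    """A (time-dependent or binary) ROC curve with its trapezoidal AUC.

    ``points`` has one row per swept threshold with columns
    ``threshold``, ``sensitivity``, ``specificity``.
    """

    points: pd.DataFrame
    auc: float
    horizon: float | None = None


@dataclass
class PairIndexModel:
    """A fitted pair-based prognostic index.

    The index of a sample is ``sum_i coefficients[p_i] * pair_score(p_i)``;
    samples with index strictly above ``cutoff`` fall in the high-risk group.
    """

    selected_pairs: list[str]
    coefficients: dict[str, float]
    cutoff: float
    roc_time: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.selected_pairs) != set(self.coefficients):
            raise SchemaError("coefficients must be keyed exactly by selected_pairs")
        if not np.isfinite(self.cutoff):
            raise DomainError("cutoff must be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_pairs": list(self.selected_pairs),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "cutoff": float(self.cutoff),
            "roc_time": float(self.roc_time),
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PairIndexModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            selected_pairs=list(payload["selected_pairs"]),
            coefficients=dict(payload["coefficients"]),
            cutoff=float(payload["cutoff"]),
            roc_time=float(payload["roc_time"]),
            training_meta=payload.get("training_meta", {}),
        )


@dataclass
class RiskAssignment:
    """Per-sample index scores and the derived high/low risk groups."""

    scores: pd.Series
    group: pd.Series  # values in {"high", "low"}
    cutoff: float

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.group.index):
            raise SchemaError("scores and group must share one sample index")
        expected = np.where(self.scores.to_numpy() > self.cutoff, "high", "low")
        if not (self.group.to_numpy() == expected).all():
            raise DomainError("group labels inconsistent with scores and cutoff")

    @property
    def high_ids(self) -> pd.Index:
        return self.group.index[self.group == "high"]

    @property
    def low_ids(self) -> pd.Index:
        return self.group.index[self.group == "low"]


@dataclass
class CompositeIndexModel:
    """Composite clinical + pair-index model: a linear score over encoded features.

    ``terms`` is an ordered list of (feature name, coefficient); ``encodings``
    records how each raw clinical column was turned into the numeric feature
    (see :func:`tcrpi.index_model.encode_clinical`), so the score can be
    recomputed exactly on new samples.
    """

    terms: list[tuple[str, float]]
    encodings: dict

    def score(self, features: pd.DataFrame) -> pd.Series:
        """Linear composite score for already-encoded feature columns."""
        missing = [name for name, _ in self.terms if name not in features.columns]
        if missing:
            raise SchemaError(f"encoded features missing columns: {missing}")
        out = pd.Series(0.0, index=features.index)
        for name, coef in self.terms:
            out = out + coef * features[name].astype(float)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {"terms": [[n, float(c)] for n, c in self.terms], "encodings": self.encodings}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompositeIndexModel":
        payload = json.loads(Path(path).read_text())
        return cls(terms=[(n, float(c)) for n, c in payload["terms"]], encodings=payload["encodings"])


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the distinct observed event times in increasing order
    (with 0 prepended), ``survival`` the estimate just after each time, and
    ``n_at_risk`` the risk-set size at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("KM times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise DomainError("KM survival must be non-increasing")
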