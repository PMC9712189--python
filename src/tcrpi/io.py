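"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as gene x sample TSV (first column gene id,
header row of sample ids); gene sets as GMT (set name, description, then
tab-separated gene ids); clinical tables as CSV with a fixed column set;
fitted models as JSON (see :mod:`tcrpi.datatypes`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort
from .errors import SchemaError
from .synthetic import CLINICAL_COLUMNS


def read_expression_tsv(path: str | Path, cohort_id: str | None = None) -> ExpressionCohort:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionCohort(values=df, cohort_id=cohort_id or Path(path).stem)


def write_expression_tsv(cohort: ExpressionCohort, path: str | Path) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}:{line_no}: GMT line needs name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise SchemaError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "tcrpi")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c != "response"]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    if "response" not in df.columns:
        df["response"] = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicated sample id {dup!r} in clinical table")
    if (df["os_months"].dropna() <= 0).any():
        raise SchemaError("os_months must be positive")
    if not df["os_event"].dropna().isin([0, 1]).all():
        raise SchemaError("os_event must be 0/1")
    return df


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def write_pair_matrix_tsv(pm: pd.DataFrame, path: str | Path) -> None:
    pm.to_csv(path, sep="\t", index_label="pair_id")


def read_pair_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pair_id")


def write_enrichment_tsv(nes: pd.DataFrame, path: str | Path) -> None:
    nes.to_csv(path, sep="\t", index_label="cell_type")


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_type")
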