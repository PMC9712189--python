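"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order: score every cohort with ssGSEA, pool and
normalize, build and prune the binary pair matrix on the pooled samples,
split 1:1:1:1, screen pairs by training log-rank, fit the LASSO Cox and
the final multivariate Cox on the training quarter only, freeze the index
and its ROC cutoff, and only then evaluate every part (and the responder
cohort, when labels exist).  One global seed fans out deterministically to
the per-stage seeds, so identical configuration + seed means identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_pair import build_pair_matrix, filter_constant_pairs
from .datatypes import (
    CompositeIndexModel,
    ExpressionCohort,
    PairIndexModel,
    RiskAssignment,
)
from .enrichment import DEFAULT_ALPHA, normalize_enrichment, ssgsea_matrix
from .errors import ConfigurationError, SchemaError
from .evaluation import (
    binary_roc_auc,
    dichotomize_response,
    harrell_cindex,
    rms_ratio_by_group,
)
from .index_model import (
    assign_risk,
    compute_tcrpi,
    fit_ctcpi,
    fit_final_cox,
    fit_lasso_cox,
    logrank_test,
    select_cutoff,
    select_prognostic_pairs,
    split_cohort,
    time_dependent_roc,
)
from .io import (
    read_clinical_csv,
    read_expression_tsv,
    read_gmt,
    write_clinical_csv,
    write_enrichment_tsv,
    write_expression_tsv,
    write_gmt,
    write_pair_matrix_tsv,
)
from .synthetic import SimulationConfig, generate_study

logger = logging.getLogger(__name__)

PART_NAMES = ["training", "testing1", "testing2", "testing3"]


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed.

    Uses :class:`numpy.random.SeedSequence` spawn keys indexed by a fixed
    stage registry, truncated below 2**31 so the value is usable anywhere a
    small integer seed is expected.
    """
    stages = ["simulate", "split", "lasso", "bootstrap"]
    if stage not in stages:
        raise ConfigurationError(f"unknown seeded stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stages.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisParams:
    """Tunables of the analysis itself (as opposed to the data source)."""

    alpha_ssgsea: float = DEFAULT_ALPHA
    logrank_alpha: float = 0.05
    lasso_folds: int = 10
    lambda_rule: str = "min"
    final_retention: str = "wald"
    roc_time_months: float = 60.0
    rms_tau_months: float = 120.0
    ctcpi_encodings: dict = field(default_factory=dict)
    frequency_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("logrank_alpha",):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.roc_time_months <= 0 or self.rms_tau_months <= 0:
            raise ConfigurationError("time horizons must be positive")


@dataclass
class AnalysisResult:
    """Everything the fitted analysis produced, for reporting and reuse."""

    nes: pd.DataFrame
    pair_matrix: pd.DataFrame
    parts: dict[str, list[str]]
    prognostic_pairs: list[str]
    lasso_support: list[str]
    model: PairIndexModel
    risk: RiskAssignment
    ctcpi: CompositeIndexModel
    ctcpi_scores: pd.Series
    metrics: dict
    clinical: pd.DataFrame


def validate_inputs(
    cohorts: Sequence[ExpressionCohort],
    gene_sets: Mapping[str, Sequence[str]],
    clinical: pd.DataFrame,
) -> dict:
    """Cross-check identifiers between expression, gene sets and clinical.

    Returns counts of dropped entities; raises :class:`SchemaError` when
    the expression/clinical sample intersection is empty.
    """
    expr_ids: list[str] = []
    for cohort in cohorts:
        expr_ids.extend(cohort.sample_ids)
    if len(set(expr_ids)) != len(expr_ids):
        dup = pd.Index(expr_ids)
        raise SchemaError(f"sample id {dup[dup.duplicated()][0]!r} appears in multiple cohorts")
    shared = set(expr_ids) & set(clinical.index)
    if not shared:
        raise SchemaError("no samples shared between expression and clinical table")
    dropped_clinical = len(clinical) - len(shared)
    dropped_expression = len(expr_ids) - len(shared)
    if dropped_clinical:
        logger.info("dropping %d clinical-only samples", dropped_clinical)
    if dropped_expression:
        logger.info("dropping %d expression-only samples", dropped_expression)
    missing_genes = {}
    for cohort in cohorts:
        for name, members in gene_sets.items():
            absent = len(set(members) - set(cohort.gene_ids))
            if absent:
                missing_genes[(cohort.cohort_id, name)] = absent
                logger.info(
                    "cohort %s: %d gene(s) of set %s absent; set restricted per cohort",
                    cohort.cohort_id,
                    absent,
                    name,
                )
    return {
        "n_samples": len(shared),
        "dropped_clinical_samples": dropped_clinical,
        "dropped_expression_samples": dropped_expression,
        "missing_set_genes": sum(missing_genes.values()),
    }


def run_analysis(
    cohorts: Sequence[ExpressionCohort],
    gene_sets: Mapping[str, Sequence[str]],
    clinical: pd.DataFrame,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Fit the pair index end to end on a pooled multi-cohort study."""
    params = params or AnalysisParams()
    validate_inputs(cohorts, gene_sets, clinical)

    # 1. per-cohort enrichment, pooled and normalized
    raw = pd.concat(
        [ssgsea_matrix(c, gene_sets, alpha=params.alpha_ssgsea) for c in cohorts], axis=1
    )
    nes = normalize_enrichment(raw)

    # 2. pair features on the pooled sample set, constants removed
    pm_all = build_pair_matrix(nes)
    pm = filter_constant_pairs(pm_all, frequency_band=params.frequency_band)

    # 3. restrict to samples with survival, split 1:1:1:1
    surv = clinical.loc[clinical.index.intersection(pm.columns)]
    surv = surv[surv["os_months"].notna() & surv["os_event"].notna()]
    pm = pm[surv.index]
    time = surv["os_months"].astype(float)
    event = surv["os_event"].astype(int)
    part_lists = split_cohort(list(surv.index), seed=derive_seed(seed, "split"))
    parts = dict(zip(PART_NAMES, part_lists))
    train_ids = parts["training"]

    # 4. training-only selection and fitting
    prognostic = select_prognostic_pairs(
        pm[train_ids], time, event, alpha=params.logrank_alpha
    )
    if not prognostic:
        raise SchemaError("no pair passed the log-rank screen; nothing to fit")
    X_train = pm.loc[prognostic, train_ids].T.astype(float)
    lasso_coef, lasso_meta = fit_lasso_cox(
        X_train,
        time,
        event,
        folds=params.lasso_folds,
        seed=derive_seed(seed, "lasso"),
        lambda_rule=params.lambda_rule,
    )
    support = lasso_coef.index[lasso_coef != 0].tolist()
    if not support:
        raise SchemaError("LASSO kept no pair; the index cannot be built")
    final_coef = fit_final_cox(
        X_train[support], time, event, retention=params.final_retention
    )
    if final_coef.empty:
        logger.warning("Wald retention emptied the model; falling back to the LASSO support")
        final_coef = fit_final_cox(X_train[support], time, event, retention="keep_all")

    # 5. freeze the index: scores, training ROC, cutoff
    scores = compute_tcrpi(pm, final_coef.to_dict())
    roc = time_dependent_roc(
        scores.loc[train_ids],
        time.loc[train_ids].to_numpy(),
        event.loc[train_ids].to_numpy(),
        t_star=params.roc_time_months,
    )
    cutoff = select_cutoff(roc)
    model = PairIndexModel(
        selected_pairs=list(final_coef.index),
        coefficients={k: float(v) for k, v in final_coef.items()},
        cutoff=cutoff,
        roc_time=params.roc_time_months,
        training_meta={
            "seed": seed,
            "lambda_rule": params.lambda_rule,
            "penalty": lasso_meta.get("penalty"),
            "folds": params.lasso_folds,
            "n_train": len(train_ids),
            "training_auc": roc.auc,
            "n_prognostic_pairs": len(prognostic),
            "n_lasso_support": len(support),
        },
    )
    risk = assign_risk(scores, cutoff)

    # 6. composite clinical index on the training quarter
    train_risk = assign_risk(scores.loc[train_ids], cutoff)
    ctcpi = fit_ctcpi(
        train_risk,
        surv.loc[train_ids],
        time,
        event,
        encodings=params.ctcpi_encodings or None,
    )
    from .index_model import encode_clinical  # local to avoid cycle at import time

    encoded_all = encode_clinical(surv, risk, ctcpi.encodings)
    ctcpi_scores = ctcpi.score(encoded_all)

    # 7. evaluation on every part and the pooled set
    metrics = evaluate_parts(risk, ctcpi_scores, surv, parts, params)
    return AnalysisResult(
        nes=nes,
        pair_matrix=pm,
        parts=parts,
        prognostic_pairs=prognostic,
        lasso_support=support,
        model=model,
        risk=risk,
        ctcpi=ctcpi,
        ctcpi_scores=ctcpi_scores,
        metrics=metrics,
        clinical=surv,
    )


def evaluate_parts(
    risk: RiskAssignment,
    ctcpi_scores: pd.Series,
    clinical: pd.DataFrame,
    parts: Mapping[str, Sequence[str]],
    params: AnalysisParams,
) -> dict:
    """Per-part and pooled survival metrics, plus response AUC when available."""
    time = clinical["os_months"].astype(float)
    event = clinical["os_event"].astype(int)
    groups = {**{k: list(v) for k, v in parts.items()}, "entire": list(clinical.index)}
    out: dict = {"parts": {}}
    for name, ids in groups.items():
        ids = pd.Index(ids)
        sub_scores = risk.scores.loc[ids]
        sub_group = risk.group.loc[ids]
        entry: dict = {"n": len(ids), "n_high": int((sub_group == "high").sum())}
        hi = ids[sub_group == "high"]
        lo = ids[sub_group == "low"]
        if len(hi) and len(lo):
            stat, p = logrank_test(
                time.loc[hi].to_numpy(),
                event.loc[hi].to_numpy(),
                time.loc[lo].to_numpy(),
                event.loc[lo].to_numpy(),
            )
            entry["logrank_p"] = p
            entry["rms_ratio"] = rms_ratio_by_group(
                assign_risk(sub_scores, risk.cutoff), time, event, params.rms_tau_months
            )
        entry["cindex_tcrpi"] = harrell_cindex(
            sub_scores.to_numpy(), time.loc[ids].to_numpy(), event.loc[ids].to_numpy()
        )
        csub = ctcpi_scores.reindex(ids).dropna()
        if len(csub) > 1:
            entry["cindex_ctcpi"] = harrell_cindex(
                csub.to_numpy(), time.loc[csub.index].to_numpy(), event.loc[csub.index].to_numpy()
            )
        out["parts"][name] = entry
    response = dichotomize_response(clinical["response"]).dropna()
    if len(response) and response.nunique() == 2:
        # low index should mark responders, so score responders with -index
        out["response_auc"] = binary_roc_auc(
            -risk.scores.loc[response.index].to_numpy(), response.to_numpy()
        )
        out["response_n"] = int(len(response))
    return out


# ---------------------------------------------------------------------------
# File-level orchestration


@dataclass
class RunConfig:
    """Top-level run configuration (YAML-serializable)."""

    mode: str = "simulate"  # "simulate" | "load"
    simulation: SimulationConfig | None = None
    expression_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    clinical_path: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        load_inputs = bool(self.expression_paths or self.gmt_path or self.clinical_path)
        if self.mode == "simulate" and load_inputs:
            raise ConfigurationError("simulate mode must not set load-mode input paths")
        if self.mode == "load" and not (
            self.expression_paths and self.gmt_path and self.clinical_path
        ):
            raise ConfigurationError(
                "load mode needs expression_paths, gmt_path and clinical_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        par = raw.pop("params", None)
        return cls(
            simulation=SimulationConfig(**sim) if sim else None,
            params=AnalysisParams(**par) if par else AnalysisParams(),
            **raw,
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def load_study(config: RunConfig):
    cohorts = [read_expression_tsv(p) for p in config.expression_paths]
    gene_sets = read_gmt(config.gmt_path)
    clinical = read_clinical_csv(config.clinical_path)
    return cohorts, gene_sets, clinical


def write_study(outdir: Path, cohorts, gene_sets, clinical, truth=None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort in cohorts:
        write_expression_tsv(cohort, outdir / f"expression_{cohort.cohort_id}.tsv")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    write_clinical_csv(clinical, outdir / "clinical.csv")
    if truth is not None:
        gt = pd.DataFrame(
            {"true_risk": truth.true_risk, "active_true_pairs": truth.active_counts}
        )
        gt.to_csv(outdir / "ground_truth.csv", index_label="sample_id")
        pd.Series(
            ["|".join(p) for p in truth.true_pairs], name="pair_id"
        ).to_csv(outdir / "ground_truth_pairs.csv", index=False)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Execute the configured analysis and (optionally) write all artifacts."""
    if config.mode == "simulate":
        sim = config.simulation or SimulationConfig(seed=derive_seed(config.seed, "simulate"))
        cohorts, gene_sets, clinical, _truth = generate_study(sim)
    else:
        cohorts, gene_sets, clinical = load_study(config)

    result = run_analysis(cohorts, gene_sets, clinical, config.params, seed=config.seed)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_enrichment_tsv(result.nes, outdir / "enrichment_nes.tsv")
        write_pair_matrix_tsv(result.pair_matrix, outdir / "pair_matrix.tsv")
        result.model.to_json(outdir / "pair_index_model.json")
        result.ctcpi.to_json(outdir / "composite_index_model.json")
        risk_df = pd.DataFrame(
            {"tcrpi": result.risk.scores, "group": result.risk.group}
        )
        risk_df["ctcpi"] = result.ctcpi_scores.reindex(risk_df.index)
        risk_df.to_csv(outdir / "risk_assignment.csv", index_label="sample_id")
        (outdir / "metrics.json").write_text(json.dumps(result.metrics, indent=2, sort_keys=True))
        rows = [
            {"part": name, **entry} for name, entry in result.metrics["parts"].items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        provenance = {
            "package_version": __version__,
            "config": _jsonable(config.to_dict()),
            "seed": config.seed,
            "stage_seeds": {s: derive_seed(config.seed, s) for s in ("split", "lasso")},
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
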