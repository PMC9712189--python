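"""Synthetic multi-cohort study generator with a planted pair signature.

The generator emulates the data situation the pipeline is built for: many
expression cohorts profiled on different platforms, pooled into one
meta-cohort with survival and clinical annotations.  It plants a known
signal so every downstream stage has a ground truth to recover:

* latent per-sample cell-type abundances drive an additive shift on the
  genes of that cell type's set;
* a configured subset of cell-type pairs is "true": a sample's hazard is
  multiplied by ``exp(pair_log_hazard)`` for every true pair whose first
  type is more abundant than its second in that sample;
* independent clinical covariates (age > 65, stage III-IV) contribute
  their own log-hazards;
* survival times are exponential under the resulting proportional-hazards
  model, with independent uniform censoring tuned to the requested rate;
* one designated cohort (the last) carries immunotherapy response labels,
  drawn with responder probability logistic in minus the true risk;
* each cohort receives gene-level batch offsets and each sample a strictly
  increasing affine distortion, emulating platform differences that a
  rank-based method must shrug off.

All randomness flows through ``SimulationConfig.seed``; the same
configuration always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cell_pair import canonical_pair, enumerate_pairs
from .datatypes import ExpressionCohort, pair_label
from .errors import ConfigurationError

CLINICAL_COLUMNS = [
    "os_months",
    "os_event",
    "age_years",
    "gender",
    "stage",
    "grade",
    "response",
]

STAGES = ["I", "II", "III", "IV"]
RESPONSE_LEVELS = ["CR", "PR", "SD", "PD"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the synthetic generator.

    The defaults mirror the scale of the real application: a meta-cohort of
    four parts of about 800 samples each (so the training quarter after a
    1:1:1:1 split holds ~800 samples), 19 cell-type sets, and a handful of
    true pairs each multiplying the hazard by ``exp(pair_log_hazard)``.
    Time is measured in months throughout.
    """

    n_cohorts: int = 4
    samples_per_cohort: int = 800
    n_genes: int = 500
    n_cell_types: int = 19
    genes_per_set: int = 15
    n_true_pairs: int = 4
    pair_log_hazard: float = 1.0
    clinical_log_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.6, "stage": 0.5}
    )
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.002  # events per month for a zero-risk sample
    response_link_slope: float = 1.0
    seed: int = 0
    # Secondary realism knobs (fixed study conditions, not fitting targets).
    abundance_effect: float = 2.5  # expression shift per abundance s.d.
    gene_noise_sd: float = 1.0
    batch_sd: float = 0.4  # per-cohort gene-level offset s.d.
    set_overlap: int = 0  # genes each set additionally shares with others

    def __post_init__(self) -> None:
        def require(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigurationError(msg)

        require(self.n_cohorts >= 1, "n_cohorts must be positive")
        require(self.samples_per_cohort >= 20, "samples_per_cohort must be at least 20")
        require(self.n_genes >= 1, "n_genes must be positive")
        require(self.n_cell_types >= 2, "n_cell_types must be at least 2")
        require(self.genes_per_set >= 1, "genes_per_set must be positive")
        max_pairs = self.n_cell_types * (self.n_cell_types - 1) // 2
        require(
            1 <= self.n_true_pairs <= max_pairs,
            f"n_true_pairs must lie in [1, {max_pairs}] for {self.n_cell_types} cell types",
        )
        require(
            self.genes_per_set * self.n_cell_types <= self.n_genes,
            "genes_per_set * n_cell_types must not exceed n_genes (sets are disjoint)",
        )
        require(0 <= self.censoring_rate < 1, "censoring_rate must lie in [0, 1)")
        require(self.baseline_hazard > 0, "baseline_hazard must be positive")
        require(self.gene_noise_sd > 0, "gene_noise_sd must be positive")
        require(self.set_overlap >= 0, "set_overlap must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests; never read by the pipeline."""

    cell_abundance: pd.DataFrame  # cell type x sample latent abundances
    true_pairs: list[tuple[str, str]]
    true_risk: pd.Series  # per-sample linear predictor on the log-hazard scale
    active_counts: pd.Series  # per-sample count of active true pairs


def _tune_uniform_censoring(event_times: np.ndarray, rate: float) -> float:
    """Upper bound c of a U(0, c) censoring law hitting the target censoring rate.

    A sample is censored when C < T; with C ~ U(0, c) that has probability
    E[min(T, c)] / c, which decreases in c, so the target rate is found by
    root-finding on a bracket.
    """

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(event_times, c)) / c)

    lo, hi = 1e-6, float(event_times.max()) * 10 + 1.0
    if frac(hi) > rate:  # even huge horizons censor more than requested
        return hi
    return float(brentq(lambda c: frac(c) - rate, lo, hi, xtol=1e-8))


def sample_survival_times(
    linear_predictor: np.ndarray,
    baseline_hazard: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times with uniform censoring.

    Hazard of sample i is ``baseline_hazard * exp(linear_predictor[i])``.
    Returns (observed time in months, event indicator).
    """
    eta = np.asarray(linear_predictor, dtype=float)
    rates = baseline_hazard * np.exp(eta)
    event_times = rng.exponential(1.0 / rates)
    if censoring_rate <= 0:
        return np.maximum(event_times, 1e-8), np.ones(len(eta), dtype=int)
    cmax = _tune_uniform_censoring(event_times, censoring_rate)
    censor_times = rng.uniform(0.0, cmax, size=len(eta))
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return np.maximum(observed, 1e-8), event


def _choose_true_pairs(
    cell_types: Sequence[str], n_true_pairs: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Prefer pairs over disjoint cell types so each pair is independently attributable."""
    if 2 * n_true_pairs <= len(cell_types):
        chosen = rng.choice(len(cell_types), size=2 * n_true_pairs, replace=False)
        return sorted(
            canonical_pair(cell_types[chosen[2 * i]], cell_types[chosen[2 * i + 1]])
            for i in range(n_true_pairs)
        )
    universe = enumerate_pairs(cell_types)
    idx = rng.choice(len(universe), size=n_true_pairs, replace=False)
    return sorted(universe[i] for i in idx)


def build_gene_sets(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Disjoint gene sets, plus optional shared genes when set_overlap > 0."""
    genes = [f"G{j:05d}" for j in range(config.n_genes)]
    cell_types = [f"T{i:02d}" for i in range(1, config.n_cell_types + 1)]
    sets: dict[str, list[str]] = {}
    for i, name in enumerate(cell_types):
        start = i * config.genes_per_set
        sets[name] = genes[start : start + config.genes_per_set]
    if config.set_overlap > 0:
        core = genes[: config.genes_per_set * config.n_cell_types]
        for name in cell_types:
            pool = [g for g in core if g not in sets[name]]
            extra = rng.choice(len(pool), size=min(config.set_overlap, len(pool)), replace=False)
            sets[name] = sets[name] + [pool[j] for j in sorted(extra)]
    return sets


def generate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionCohort], dict[str, list[str]], pd.DataFrame, GroundTruth]:
    """Generate cohorts, gene sets, a clinical table and the planted ground truth.

    Returns ``(cohorts, gene_sets, clinical, truth)`` where ``clinical`` is a
    DataFrame indexed by sample id with columns ``os_months, os_event,
    age_years, gender, stage, grade, response`` (response is set only for
    the last cohort, emulating that only treated series carry it).
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_design, rng_clin, rng_surv, rng_expr, rng_resp = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    genes = [f"G{j:05d}" for j in range(cfg.n_genes)]
    cell_types = [f"T{i:02d}" for i in range(1, cfg.n_cell_types + 1)]
    gene_sets = build_gene_sets(cfg, rng_design)
    true_pairs = _choose_true_pairs(cell_types, cfg.n_true_pairs, rng_design)

    n_total = cfg.n_cohorts * cfg.samples_per_cohort
    sample_ids = [
        f"C{c + 1}S{i:04d}" for c in range(cfg.n_cohorts) for i in range(cfg.samples_per_cohort)
    ]
    cohort_of = np.repeat(np.arange(cfg.n_cohorts), cfg.samples_per_cohort)

    abundance = pd.DataFrame(
        rng_design.standard_normal((cfg.n_cell_types, n_total)),
        index=cell_types,
        columns=sample_ids,
    )

    # Active true pairs per sample, judged on the latent abundances.
    active = np.zeros(n_total, dtype=int)
    for a, b in true_pairs:
        active += (abundance.loc[a].to_numpy() > abundance.loc[b].to_numpy()).astype(int)

    # Independent clinical covariates.
    age = np.clip(rng_clin.normal(68.0, 10.0, n_total), 30.0, 92.0)
    gender = np.where(rng_clin.uniform(size=n_total) < 0.75, "male", "female")
    stage = np.array(STAGES)[rng_clin.choice(4, size=n_total, p=[0.15, 0.25, 0.35, 0.25])]
    grade = np.where(rng_clin.uniform(size=n_total) < 0.7, "high", "low")

    h = dict(cfg.clinical_log_hazards)
    true_risk = (
        cfg.pair_log_hazard * active
        + h.get("age", 0.0) * (age > 65.0)
        + h.get("stage", 0.0) * np.isin(stage, ["III", "IV"])
    )

    time, event = sample_survival_times(
        true_risk, cfg.baseline_hazard, cfg.censoring_rate, rng_surv
    )

    # Response labels for the designated (last) cohort only.
    response = np.full(n_total, None, dtype=object)
    last = cohort_of == cfg.n_cohorts - 1
    if last.any():
        centered = true_risk[last] - np.median(true_risk)
        p_resp = expit(-cfg.response_link_slope * centered)
        is_resp = rng_resp.uniform(size=last.sum()) < p_resp
        split_r = rng_resp.uniform(size=last.sum())
        labels = np.where(
            is_resp,
            np.where(split_r < 0.3, "CR", "PR"),
            np.where(split_r < 0.4, "SD", "PD"),
        )
        response[last] = labels

    clinical = pd.DataFrame(
        {
            "os_months": time,
            "os_event": event,
            "age_years": age,
            "gender": gender,
            "stage": stage,
            "grade": grade,
            "response": response,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # Expression: shared gene baselines, cohort batch offsets, set-level
    # abundance shifts, gene noise, then a per-sample monotone distortion.
    baseline = rng_expr.normal(6.0, 1.0, cfg.n_genes)
    gene_pos = {g: j for j, g in enumerate(genes)}
    cohorts: list[ExpressionCohort] = []
    for c in range(cfg.n_cohorts):
        mask = cohort_of == c
        ids = [sid for sid, m in zip(sample_ids, mask) if m]
        n_c = len(ids)
        batch = rng_expr.normal(0.0, cfg.batch_sd, cfg.n_genes)
        expr = (
            baseline[:, None]
            + batch[:, None]
            + rng_expr.normal(0.0, cfg.gene_noise_sd, (cfg.n_genes, n_c))
        )
        for ct in cell_types:
            rows = [gene_pos[g] for g in gene_sets[ct]]
            expr[rows, :] += cfg.abundance_effect * abundance.loc[ct, ids].to_numpy()[None, :]
        slope = np.exp(rng_expr.normal(0.0, 0.2, n_c))
        intercept = rng_expr.normal(0.0, 0.5, n_c)
        expr = expr * slope[None, :] + intercept[None, :]
        cohorts.append(
            ExpressionCohort(
                values=pd.DataFrame(expr, index=genes, columns=ids), cohort_id=f"cohort{c + 1}"
            )
        )

    truth = GroundTruth(
        cell_abundance=abundance,
        true_pairs=true_pairs,
        true_risk=pd.Series(true_risk, index=sample_ids, name="true_risk"),
        active_counts=pd.Series(active, index=sample_ids, name="active_true_pairs"),
    )
    return cohorts, gene_sets, clinical, truth


# ---------------------------------------------------------------------------
# Monotone per-sample distortions


def apply_monotone_distortion(
    cohort: ExpressionCohort, family: Mapping[str, object], seed: int = 0
) -> ExpressionCohort:
    """Pass every sample of a cohort through a strictly increasing map.

    ``family`` selects the map:

    * ``{"family": "affine", "slope": s > 0, "intercept": b}`` — ``s*x + b``;
    * ``{"family": "exponential", "scale": s > 0}`` — ``exp(x / s)``;
    * ``{"family": "random-affine", "slope_sd": v, "intercept_sd": w}`` —
      an independent affine map per sample with log-normal slopes
      (seeded by ``seed``).

    Within every sample the gene ranking is unchanged; the values differ.
    Non-monotone requests (non-positive slope or scale) raise
    :class:`ConfigurationError`.
    """
    spec = dict(family)
    kind = spec.get("family")
    values = cohort.values.to_numpy(dtype=float)
    if kind == "affine":
        slope = float(spec.get("slope", 1.0))
        intercept = float(spec.get("intercept", 0.0))
        if slope <= 0:
            raise ConfigurationError(f"affine distortion needs slope > 0, got {slope}")
        out = slope * values + intercept
    elif kind == "exponential":
        scale = float(spec.get("scale", 1.0))
        if scale <= 0:
            raise ConfigurationError(f"exponential distortion needs scale > 0, got {scale}")
        out = np.exp(values / scale)
    elif kind == "random-affine":
        slope_sd = float(spec.get("slope_sd", 0.3))
        intercept_sd = float(spec.get("intercept_sd", 1.0))
        if slope_sd < 0 or intercept_sd < 0:
            raise ConfigurationError("random-affine distortion needs non-negative spreads")
        rng = np.random.default_rng(seed)
        slopes = np.exp(rng.normal(0.0, slope_sd, values.shape[1]))
        intercepts = rng.normal(0.0, intercept_sd, values.shape[1])
        out = values * slopes[None, :] + intercepts[None, :]
    else:
        raise ConfigurationError(f"unknown distortion family {kind!r}")
    return ExpressionCohort(
        values=pd.DataFrame(out, index=cohort.gene_ids, columns=cohort.sample_ids),
        cohort_id=cohort.cohort_id,
    )
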