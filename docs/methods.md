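# Methods

This note documents the statistical machinery, the synthetic study design,
and the choices made where the method leaves room for interpretation.

## Single-sample enrichment scoring

Each sample is scored against each cell-type gene set with the
single-sample GSEA running-sum statistic (Barbie et al. style). Within a
sample, genes receive average ranks by expression (the top gene holds rank
N). Walking the genes in decreasing order, the score is

S = Σ_i [ P_in(i) − P_out(i) ],

where P_in is the in-set cumulative distribution weighted by |rank|^α and
P_out the unweighted out-of-set cumulative distribution. The exponent
defaults to α = 0.25, the established ssGSEA default; it is configurable.
Ties receive average ranks (deterministic and symmetric); the walk order
among tied genes is fixed by gene position, which is itself invariant
under strictly increasing transforms, so the whole statistic is a pure
rank functional of the sample.

Scores are normalized by dividing the pooled cell-type × sample matrix by
its global range, so the matrix spans one unit. Since this rescales every
sample by one positive constant, it provably cannot change any
within-sample comparison; the test suite asserts that the downstream pair
matrix is identical whether built from raw or normalized scores. Scoring
is per cohort (per-sample scores do not depend on other samples), and the
gene universe of a cohort is the set of genes present in its matrix; gene
set members absent from a cohort are dropped for that cohort with a
logged warning.

## Pair features

For cell types a < b (lexicographic canonical order) the pair feature is
the strict indicator NES_a > NES_b; ties score 0 (a measure-zero event
for continuous scores, but the convention is fixed and tested). With 19
cell types the universe has 171 pairs. "Constant" pairs are those whose
feature shows no variation over the pooled analysis samples — read
strictly (both a 0 and a 1 must occur); an optional frequency-band filter
(e.g. keep pairs with 1-frequency in [0.2, 0.8]) is available but off by
default. Constant-pair filtering happens on the pooled sample set before
the train/test split, mirroring the intended order of operations.

## Index fitting

* **Split** — simple random 1:1:1:1 partition (sizes differ by at most
  one), seeded; stratified-by-cohort splitting is not implemented.
* **Screen** — per-pair two-group log-rank test on the training quarter;
  pairs with p < 0.05 proceed. Pairs with an empty group are skipped with
  a warning.
* **LASSO Cox** — L1-penalized Cox partial likelihood (coordinate-descent
  Coxnet). The penalty path is generated on the training data; the
  held-out Breslow partial-likelihood deviance is accumulated over 10
  seeded folds; the default rule takes the deviance minimizer, with a
  1-standard-error alternative.
* **Final model** — the LASSO support is refit by unpenalized multivariate
  Cox; features with Wald p < 0.05 are retained and refit, and those
  coefficients are the index weights (a keep-all mode exists). The index
  of a sample is the coefficient-weighted sum of its binary pair features.
* **Cutoff** — time-dependent ROC of the training index at 60 months,
  using the cumulative-case / dynamic-control construction with
  Kaplan–Meier survival estimates (Heagerty–Lumley–Pepe). Sensitivity and
  specificity are clipped to [0, 1] (the KM plug-in can stray outside);
  the AUC integrates the curve along its threshold parametrization. The
  cutoff is the observed threshold minimizing the Euclidean distance to
  the corner (0, 1) in (1 − specificity, sensitivity) space; ties break
  to the smaller threshold. Risk groups use strict ">" (a score exactly at
  the cutoff is low-risk), mirroring the strict pair-score convention.

## Composite index

Candidate features: age (dichotomized at >65 years), gender (male = 1),
stage (III–IV = 1), grade (high = 1) and the pair index. All enter a
multivariable Cox model on complete cases; features at Wald p < 0.05 are
retained and refit, and the composite score is their linear combination.
Samples missing survival are excluded from all fitting; samples missing a
clinical covariate are excluded only from composite fitting. The pair
index enters **continuously** by default: entering it as the dichotomized
risk-group indicator caps the composite's concordance at the information
content of a binary split and routinely leaves the composite *below* the
continuous index it contains, defeating the purpose of the composite. The
indicator encoding (`{"kind": "group"}`), a continuous age, and an
ordinal stage are all available through the encoding configuration and are
serialized with the model so it can be re-applied exactly.

## Evaluation

Kaplan–Meier curves and two-group log-rank tests quantify risk-group
separation per part. Harrell's C-index treats a pair of subjects as
comparable iff the shorter observed time is an event; tied event times
are not comparable unless one subject is censored later; score ties count
0.5. Restricted mean survival time is the exact step integral of the KM
curve up to τ = 120 months, and the group comparison is reported as the
low/high RMS ratio. Response prediction uses the rank-based AUC of minus
the index against the responder label (CR/PR = 1, SD/PD = 0). C-index
differences between two scores can be tested with a paired bootstrap over
subjects (1000 replicates by default, seeded). Kruskal–Wallis p-values
are asymptotic chi-square; Fisher's exact test accepts 2×2 and r×c
tables. The cytolytic activity score is the mean expression of PRF1 and
GZMA.

## Synthetic study design

The generator emulates a pooled multi-platform study at the scale of the
real application: 4 cohorts × 800 samples (so the training quarter holds
~800 samples), 19 disjoint gene sets of 15 genes within 500 genes, and
4 true pairs. Per sample, latent cell-type abundances are standard
normal; set genes are shifted additively by 2.5 × abundance against gene
noise with unit standard deviation, which makes the pair feature agree
with the latent abundance ordering for ≈95% of samples. A true pair is
"active" in a sample when its first type's latent abundance exceeds its
second's; the log-hazard is

η = 1.0 × (#active true pairs) + 0.6 × 1[age > 65] + 0.5 × 1[stage III–IV].

Event times are exponential with hazard 0.002·exp(η) per month — the
baseline chosen so that a zero-risk sample has years-scale survival and
the cohort has realistic follow-up beyond the 60-month ROC horizon.
Censoring is independent uniform on [0, c] with c tuned by root-finding
to the configured censoring fraction (0.3 by default). The last cohort
carries response labels with responder probability logistic in minus the
centered risk (responders split 30/70 into CR/PR, non-responders 40/60
into SD/PD), emulating that only treated series have response data.
Platform structure: per-cohort gene-level offsets (s.d. 0.4) and a
strictly increasing affine distortion per sample (log-normal slope,
normal intercept). Time is in months throughout; the 5- and 10-year
horizons are stored as 60 and 120 months.

What the generator does **not** emulate: probe-level microarray noise,
count-based RNA-seq distributions, or gene–gene correlation beyond the
set-level abundance signal; gene sets are disjoint by construction (an
overlap knob exists) although real curated sets overlap. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
a planted rank signal under monotone platform distortions — not
performance on real tumor cohorts.

## Numerical choices and degenerate inputs

Unpenalized Cox fits use Newton iteration with convergence precision
1e−9 (tested against an independent Newton/bisection solver to 1e−6).
The held-out CV deviance uses the Breslow tie convention; synthetic event
times are continuous so ties are measure-zero. A constant enrichment
matrix, an empty gene set, a set equal to the whole universe, tests with
zero events, ROC horizons with no prior events or nobody at risk, and
single-class AUC labels all raise typed errors rather than returning
numbers. An all-constant pair matrix is a warning (empty result), not an
error. Problem sizes in the test suite (e.g. 10 seeds at the 800-training
scale for recovery, 500 replicates for the log-rank calibration) were
chosen so the whole suite documents the method's behavior at the scale it
is meant for while remaining routine to run on a laptop.

## Known limitations

* The rank invariance holds for *within-sample* monotone distortions;
  gene-level batch effects that reorder genes within samples are only
  mitigated (by the set-level averaging of ssGSEA), not eliminated.
* The log-rank screen tests pairs marginally; strongly correlated pairs
  can enter the LASSO together, and the Wald-retention step then decides
  among them — with correlated features the retained set is not unique.
* The composite model assumes proportional hazards for the encoded
  clinical features and performs complete-case analysis; no imputation.
* The curated gene-set collection itself is an input (GMT), not a product
  of this package; the bundled synthetic sets are labelled as such.
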