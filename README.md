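# tcrpi

A rank-invariant **T-cell-pair prognostic index** for multi-cohort tumor
transcriptomics, with a synthetic multi-cohort study generator for
validating every stage against a known planted signal.

## The problem

Survival signatures trained on pooled expression cohorts are fragile:
each cohort is measured on its own platform with its own dynamic range, so
absolute expression values (and anything built linearly on them) do not
transfer. This package implements a pair-based strategy that sidesteps the
problem. Curated T-cell gene sets (19 by default) are scored per sample
with single-sample GSEA; each sample is then described not by the scores
themselves but by the binary **within-sample ordering** of score pairs:

```
TCP(a, b | s) = 1  if NES_a(s) > NES_b(s),  else 0
```

For k cell types this yields k·(k−1)/2 features (171 for 19 types).
Because ssGSEA is a rank statistic and the pair feature compares two
numbers from the same sample, any strictly increasing per-sample
distortion of the expression data — i.e. a platform effect — leaves the
entire feature matrix, and therefore the fitted model, unchanged.

## The index

On a pooled meta-cohort split 1:1:1:1 into training and three test parts:

1. constant pairs (all 0 or all 1 across the pooled samples) are removed;
2. pairs whose 0/1 split separates training survival (log-rank p < 0.05)
   enter a LASSO-penalized Cox regression, penalty chosen by
   cross-validated partial-likelihood deviance;
3. the LASSO support is refit by unpenalized multivariate Cox and features
   retained at Wald p < 0.05 define

   `TCRPI(s) = Σᵢ βᵢ · TCPᵢ(s)`;

4. the risk cutoff is the threshold of the training-set time-dependent ROC
   (cumulative cases / dynamic controls at 60 months, Kaplan–Meier
   weighted) closest to the ideal corner; samples above it are high-risk;
5. a composite index (CTCPI) is fit by multivariable Cox over the index
   plus clinical covariates (age, gender, stage, grade), keeping features
   at Wald p < 0.05, e.g. `CTCPI = β_age·Age + β_stage·Stage + β·TCRPI`.

Evaluation: Kaplan–Meier curves with log-rank tests per part, Harrell's
C-index, restricted-mean-survival ratios at 120 months, and a
responder-vs-non-responder ROC/AUC on cohorts with immunotherapy response
labels (CR/PR vs SD/PD).

## Worked example

```python
from tcrpi import SimulationConfig, generate_study, run_analysis, AnalysisParams

cohorts, sets, clinical, truth = generate_study(SimulationConfig(seed=1))
result = run_analysis(cohorts, sets, clinical, AnalysisParams(), seed=1)
print(sorted(result.model.selected_pairs), result.model.cutoff)
```

This simulates four cohorts of 800 samples with four planted prognostic
pairs (per-pair log hazard 1.0) and fits the index. Output of the bundled
run at seed 1:

```
planted pairs:  ['T01|T03', 'T07|T18', 'T10|T11', 'T12|T14']
selected pairs: ['T01|T03', 'T07|T18', 'T10|T11', 'T12|T14']
coefficients:   {'T01|T03': 0.883, 'T07|T18': 0.849, 'T10|T11': 0.876, 'T12|T14': 0.84}
risk cutoff:    0.883
training AUC(60 mo): 0.849
testing1: logrank p=3.35e-33  C-index TCRPI=0.685  CTCPI=0.722  RMS ratio=2.61
testing2: logrank p=7.37e-29  C-index TCRPI=0.683  CTCPI=0.710  RMS ratio=2.37
testing3: logrank p=3.89e-36  C-index TCRPI=0.705  CTCPI=0.732  RMS ratio=2.77
composite terms: [('age', 0.554), ('stage', 0.422), ('tcrpi', 1.053)]
response AUC: 0.7
```

All four planted pairs are recovered with coefficients near the attenuated
truth; the cutoff splits every held-out part into groups with strongly
different survival; the composite index improves concordance because the
generator also gave age and stage their own hazard contributions; and low
index values predict immunotherapy response (AUC 0.70) because the
generator links responder probability to low risk.

The same pipeline is available from the shell:

```sh
tcrpi simulate --seed 1 -o study/          # write a synthetic study to disk
tcrpi run -c run.yaml                      # fit from a YAML config (simulate or load mode)
tcrpi apply --model out/pair_index_model.json --expression new_cohort.tsv \
            --gmt study/gene_sets.gmt -o risk.csv
tcrpi report --run-dir out/
```

## Layout

- `tcrpi.synthetic` — seeded multi-cohort generator with planted pair
  signature, clinical covariates, censoring and response labels
- `tcrpi.enrichment` — ssGSEA running-sum scoring and normalization
- `tcrpi.cell_pair` — pair enumeration, binarization, constant filtering
- `tcrpi.index_model` — split / log-rank screen / LASSO Cox / final Cox /
  time-dependent ROC cutoff / risk groups / composite index
- `tcrpi.evaluation` — KM, log-rank, C-index, RMS, response AUC, classical
  group statistics, cytolytic (PRF1/GZMA) score
- `tcrpi.pipeline`, `tcrpi.cli` — orchestration, I/O and the `tcrpi` CLI

See `docs/methods.md` for the statistical details and design choices.
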