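# mutlike

Classifier-score-defined subtyping of AML gene-expression cohorts:
discovery of a **mutant-like** class among *TP53* wild-type samples.

*TP53*-mutant AML is the most rapidly fatal subtype, yet some wild-type
patients fare just as badly. This package implements the supervised
route to finding them: a ridge-penalized logistic classifier is trained
to tell mutant from wild-type expression profiles; its linear predictor
(the **ridge score** r = β₀ + xᵀβ) measures how mutant-like any profile
is; wild-type samples in the top decile of ridge scores are minted as
the *mutant-like* class. A complementary wild-type-only ridge model
transfers the class to independent cohorts without their mutants ever
touching the fit, and 100 rounds of bootstrap elastic-net regression
compress the signal into a 25-gene core signature. The derived classes
are then characterized the way a cohort study would: Kaplan–Meier and
log-rank survival comparisons, pooled t-tests with Benjamini–Hochberg
FDR for clinical covariates and per-drug ex-vivo AUC z-scores, and
preranked GSEA with cross-cohort concordance filtering.

Real patient cohorts are not redistributable, so a synthetic-cohort
generator (`mutlike.simulate`) produces negative-binomial count
matrices with a planted mutant program, a hidden mutant-like wild-type
subset, and survival / drug-resistance / clinical covariates coupled to
program activation — with ground-truth labels, so every step of the
pipeline is testable for *recovery*, not just for running.

Audience: computational biologists studying expression-defined disease
subtypes, and anyone who needs a tested reference implementation of the
score-threshold subtyping idiom (train on labels, mint a class from the
score tail, validate across cohorts).

## Worked example

```python
from mutlike import (SimulationConfig, generate_cohort,
                     PipelineConfig, run_full_pipeline)
import dataclasses

cfgA = SimulationConfig(seed=11)                      # 400 samples x 2000 genes
cfgB = dataclasses.replace(cfgA, seed=1011)           # same biology, new patients
exprA, annA, drugsA, truthA = generate_cohort(cfgA)
exprB, annB, _, truthB = generate_cohort(cfgB)

rep = run_full_pipeline(exprA, annA, exprB, annB, drugsA=drugsA,
                        config=PipelineConfig(seed=11, signature_n_iter=100))
print(rep["assignment_A"].counts())
print(rep["mut_classifier_metrics"]["auroc"])
print(rep["survival_medians"])
```

Output (abridged):

```
{'WT': 328, 'MUT': 36, 'MUTLIKE': 36}
0.9564579256360078
     group    n  median_days
0      MUT   36   161.377594
1  MUTLIKE   36   235.200428
2       WT  328   569.704144
```

36 of 364 wild-type samples (top decile) are called MUTLIKE; the
held-out AUROC of the mutant classifier is 0.956; and the minted class
inherits the mutant survival phenotype — median overall survival 235
days versus 570 days for the remaining wild-type (log-rank p ≈ 5e-7),
while MUT and MUTLIKE are statistically indistinguishable (p ≈ 0.13).
Against the generator's ground truth the MUTLIKE calls match the
planted hidden subset with Jaccard ≈ 0.8, and 24 of the 25 core
signature genes fall inside the planted 50-gene program.

## Analysis walkthrough

The numbered scripts under `analysis/` re-run the whole study on
synthetic cohorts, each printing what it finds and writing tables under
`results/` (cohort TSVs land in `scratch/`):

```sh
python analysis/01_simulate_cohorts.py      # discovery + validation cohorts
python analysis/02_derive_mutlike_subtype.py
python analysis/03_survival_and_clinical.py
python analysis/04_drug_response.py
python analysis/05_enrichment.py
python analysis/06_core_signature.py
```

Library layout: `mutlike.io` (TSV/GMT I/O, CPM→log2→z normalization,
gene harmonization, stratified splits), `mutlike.glm` (penalized
logistic fits, CV penalty selection, scoring, AUROC), `mutlike.pipeline`
(decile rule, complementary model, transfer, stability-selected
signature, full orchestration), `mutlike.survival`, `mutlike.stats`,
`mutlike.enrichment`, `mutlike.simulate`. See `docs/methods.md` for the
model, all formulas, parameter defaults, and what the simulation does
and does not emulate.

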