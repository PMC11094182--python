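# Methods

## The problem

In acute myeloid leukemia (AML), mutations in *TP53* define the most
aggressive molecular subtype, but mutation status does not capture every
patient whose disease behaves that way. The hypothesis implemented here
is that a *transcriptional* state — a gene-expression program active in
mutant samples — also occurs in a minority of wild-type samples, and
that those "mutant-like" wild-type cases share the mutant phenotype:
short survival, broad ex-vivo drug resistance, lower marrow blasts and
white-cell counts. Unsupervised methods (PCA, clustering) do not expose
this subset; a supervised classifier score does.

## The derivation procedure

Let X be the genes × samples matrix of z-scored log2-CPM expression and
y the mutant indicator.

1. **Normalization.** Counts → CPM (counts / library size × 10⁶) →
   log2(CPM + 1) → per-gene z across samples (sample sd, n−1; genes with
   zero sd map to an all-zero row). Z-scoring is per cohort: each model
   sees its own cohort standardized internally.
2. **Mutant classifier.** A 60/40 stratified split; on the training
   side, L2-penalized (ridge) logistic regression minimizing

       (1/n) Σᵢ [−yᵢ log pᵢ − (1−yᵢ) log(1−pᵢ)]
           + λ [α‖β‖₁ + (1−α)/2 ‖β‖₂²],   pᵢ = σ(β₀ + xᵢᵀβ),

   with α = 0, intercept unpenalized, λ chosen by stratified 5-fold CV
   minimizing mean held-out binomial deviance (a one-standard-error rule
   is available by flag). The **ridge score** of a sample is the linear
   predictor β₀ + xᵀβ, not the probability: it is unbounded and
   comparisons of score distributions across groups are the object of
   interest; the logistic transform is also exposed.
3. **Minting the subtype.** All samples are scored with the trained
   model. Among *wild-type* samples the nearest-rank 90th percentile of
   ridge scores is the cutoff; wild-type samples strictly above it are
   labeled MUTLIKE (≈ top decile). Mutants keep the MUT label regardless
   of score. Scoring the whole cohort (training samples included)
   mirrors the study design this reproduces — the class is a descriptive
   partition of the cohort, not a held-out prediction; an out-of-fold
   scoring mode exists for the pessimistic variant.
4. **Complementary model.** To transfer the class to a cohort whose
   mutants must not influence it, a second ridge model of MUTLIKE vs WT
   is fitted on wild-type samples only. Mutant samples in its training
   matrix are a hard error, so leakage is structurally impossible. It is
   evaluated on held-out wild-type samples, then refitted on all
   wild-type samples for transfer.
5. **Transfer.** The frozen complementary model scores the second
   cohort (gene spaces harmonized by exact-id intersection first) and
   the decile rule is re-applied within that cohort's wild-type scores.
   An absolute-threshold mode is available when the first cohort's
   cutoff should be carried over instead.
6. **Core signature.** On the wild-type samples, 100 stratified
   bootstrap resamples are each fitted with elastic-net logistic
   regression (α = 0.5) at a penalty CV-selected once on the full
   target data; genes with nonzero coefficients are tallied, and the 25
   most recurrently selected genes (ties broken lexicographically) form
   the core signature. A ridge model refitted on those 25 genes alone is
   evaluated held-out. Selecting λ once rather than inside every
   bootstrap keeps the procedure deterministic and ~10× cheaper without
   changing which genes recur; `cv_per_iteration=True` restores the
   per-bootstrap CV.

## Characterization statistics

- **Survival.** Kaplan–Meier product-limit curves per group; the median
  is the smallest observed time with S(t) ≤ 0.5 (reported as missing if
  the curve never crosses 0.5). Pairwise two-group log-rank tests
  (χ² on 1 df, hypergeometric variance), events preceding censorings at
  tied times; pairwise P values are reported raw, uncorrected.
- **Clinical and drug comparisons.** Unpaired two-sample t-tests,
  pooled variance by default (Welch by flag), with Benjamini–Hochberg
  step-up FDR applied per explicit family: across the drug panel for
  drug contrasts, across clinical variables for clinical contrasts.
  Drug AUC values are z-scored per drug over non-missing samples and
  multiplied by −1, so high z = sensitive; missing values are excluded
  pairwise, never imputed.
- **Enrichment.** Genes are ranked by the per-gene Welch t statistic on
  log2-CPM (descending; ties broken by gene id). Preranked GSEA uses
  the weighted running sum (weight p = 1; p = 0 reduces to the classic
  Kolmogorov–Smirnov form), a gene-label permutation null (default
  1000 permutations), NES = ES divided by the mean |ES| of same-sign
  null values, nominal p from the same-sign null tail, and FDR from the
  null NES values pooled across sets, by sign. A phenotype-permutation
  variant (labels shuffled, full re-ranking per permutation) is
  provided; gene-label is the default for speed and determinism.
  Cross-cohort concordance keeps sets with same-sign NES and FDR < 0.05
  in both cohorts independently; the surface-marker analysis intersects
  markers concordantly differentially expressed (FDR < 0.05 in both
  cohorts, same direction) between the MUT-vs-WT and MUTLIKE-vs-WT
  comparisons, requiring agreeing direction.

## The synthetic cohort generator

Real AML cohorts are not redistributable, so the package ships a
generator that emulates the statistical structure the analysis assumes,
with ground truth for recovery tests. Per-sample **activation** a ∈
[0, 1] drives everything: a = 1 for mutants and for a hidden fraction of
wild-type samples (the planted mutant-like class), Beta(1, 10)
background noise for the rest — deliberately binary-ish, because the
derivation treats mutant-like as a discrete class and a top-decile rule
needs a discrete target.

- **Counts**: negative binomial per gene, log2-mean = baseline +
  δ·a for the 50 program genes (baseline ~ U(2, 8) log2 units),
  variance μ + φμ² with global dispersion φ = 0.3.
- **Survival**: exponential event times with hazard h₀·exp(γ·a)
  (h₀ = 1/900 events/day, γ = 1.5), independent exponential censoring
  calibrated so ≈ 30% of baseline subjects are censored.
- **Drug AUC**: per-drug baseline ~ U(80, 220) plus 30·a plus N(0, 10)
  noise — higher AUC (resistance) with activation.
- **Clinical**: blasts ~ N(70 − 25a, 12) clipped to [1, 100], WBC ~
  N(35 − 15a, 12) clipped ≥ 0.5 — both *decrease* with activation.
- Mutant and mutant-like counts are deterministic
  (round(prevalence·n), round(fraction·n_wt)), so class sizes are exact.

Defaults are 400 samples × 2000 genes, 9% mutants, 10% of wild-type
planted mutant-like, δ = 1.5 — the cohort scale and class balance of a
large discovery cohort, with an effect size chosen for testability (no
published effect-size estimate exists for the program). Gene-level
biology (program membership, baseline means, drug baselines) is drawn
from a separate `biology_seed`, so cohorts generated with different
sampling seeds represent different patients from the *same* disease —
required for cross-cohort transfer to be meaningful.

What the generator does **not** emulate: batch effects between cohorts,
gene–gene correlation beyond the single shared program, copy-number or
karyotype events, relapse trajectories, non-proportional hazards, and
covariate-dependent censoring. Passing recovery tests therefore shows
the pipeline recovers a planted discrete program under idealized
sampling; it does not certify performance on real cohorts, where the
mutant-like state may be continuous, confounded, or batch-distorted.

## Numerical choices

- Ridge and unpenalized logistic fits: scikit-learn lbfgs. Mixed
  elastic-net penalties: an in-package FISTA accelerated
  proximal-gradient solver (soft-thresholding for the L1 part, fixed
  step 1/L from the spectral norm of the design), which produces exact
  zeros and matches a generic convex optimizer's objective to < 1e-6 on
  small instances (tested) and scikit-learn saga to ~1e-7 at full scale.
- log2(CPM + 1): pseudocount 1, bounded at zero, standard for CPM.
- Nearest-rank quantile with a strict `>` at the boundary: deterministic
  and tie-safe; with n distinct wild-type scores the MUTLIKE count is
  exactly n − ⌈0.9n⌉, and fully tied scores call nobody.
- AUROC is the rank-based concordance probability with half-credit for
  ties (Mann–Whitney correspondence).
- Zero-variance guards: constant genes get z ≡ 0 and ranking statistic
  0; two constant equal groups give t = 0, p = 1; drugs with < 2
  observed values are blanked with a warning.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configs give bit-identical
  cohorts, splits, bootstraps and permutations.

## Problem sizes

The shipped analyses and tests run at 400 samples × 2000 genes with 100
signature bootstraps and 200–1000-permutation/repetition nulls; the
full two-cohort pipeline completes in a few minutes on one CPU. These
sizes were chosen so the planted effects are comfortably detectable
while the whole analysis remains quick to reproduce; every size is a
config parameter.

## Known limitations

- Transfer assumes exact gene-id overlap; no identifier mapping layer.
- The decile is a free parameter defaulting to 0.10; nothing in the
  procedure estimates the true mutant-like prevalence.
- The signature size k = 25 is a parameter, not a discovered constant.
- The complementary model's positive labels come from the first
  cohort's decile rule, so label noise there propagates to transfer.
- Log-rank pairwise P values are deliberately uncorrected, mirroring
  how such comparisons are conventionally reported in this setting.
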