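"""Synthetic AML-like cohort generator with a planted mutant program.

The generator emulates the statistical structure the subtype-discovery
pipeline assumes about a leukemia cohort:

* a minority of samples carry the driver mutation (``true_mutant``);
* a transcriptional *program* of ``n_program_genes`` genes is fully
  activated in mutants and in a hidden fraction of wild-type samples
  (``true_mutlike``), and near-silent elsewhere — per-sample
  ``activation`` is 1 for the former and small Beta(1, 10) background
  noise for the latter, so a top-decile score threshold has a discrete
  target to recover;
* RNA-seq counts are negative-binomial with log2-mean
  ``baseline + effect_size_delta * activation`` for program genes;
* overall survival is exponential with hazard
  ``baseline_hazard * exp(hazard_coef_gamma * activation)`` under
  independent exponential censoring;
* ex-vivo drug response AUC rises (resistance) with activation;
* blast percentage and white-cell count fall with activation.

Everything is driven by one :class:`SimulationConfig`; the same config
(including seed) reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, write_expression, write_annotation


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 400
    n_genes: int = 2000
    n_program_genes: int = 50
    mutant_prevalence: float = 0.09
    mutlike_fraction: float = 0.10  # fraction of wild-type samples
    effect_size_delta: float = 1.5  # log2-units added per program gene at activation 1
    baseline_log_mean_range: tuple[float, float] = (2.0, 8.0)
    dispersion: float = 0.3  # NB: var = mu + dispersion * mu^2
    hazard_coef_gamma: float = 1.5  # log-hazard per unit activation
    baseline_hazard: float = 1.0 / 900.0  # events per day for activation 0
    censor_rate: float = 0.3
    n_drugs: int = 40
    drug_resistance_coef: float = 30.0  # AUC units per unit activation
    seed: int = 0
    # gene-level biology (program membership, baseline means, drug
    # baselines) is drawn from its own seed so that cohorts simulated
    # with different sampling seeds share the same planted program, as
    # two real cohorts of the same disease would
    biology_seed: int = 424242

    def __post_init__(self) -> None:
        if self.n_samples < 0 or self.n_genes <= 0 or self.n_drugs < 0:
            raise ValueError("counts must be non-negative (n_genes positive)")
        if self.n_program_genes > self.n_genes:
            raise ValueError("n_program_genes cannot exceed n_genes")
        if not 0 < self.mutant_prevalence < 1:
            raise ValueError("mutant_prevalence must lie in (0, 1)")
        if not 0 <= self.mutlike_fraction < 1:
            raise ValueError("mutlike_fraction must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        if "baseline_log_mean_range" in data:
            data["baseline_log_mean_range"] = tuple(data["baseline_log_mean_range"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for recovery tests."""

    program_gene_ids: list[str]
    table: pd.DataFrame  # index sample_id; columns activation, true_mutant, true_mutlike


def _negative_binomial(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # mean/size parameterization: var = mu + mu^2/size with size = 1/dispersion
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one cohort.

    Returns ``(counts, annotation, drug_auc, truth)``, all sharing one
    sample ordering. Mutant and mut-like counts are applied
    deterministically: ``round(prevalence * n)`` mutants and
    ``round(mutlike_fraction * n_wt)`` planted mut-like wild-types.
    """
    cfg = config
    if cfg.n_samples == 0:
        raise ValueError("cannot simulate an empty cohort")
    rng = np.random.default_rng(cfg.seed)
    rng_bio = np.random.default_rng(cfg.biology_seed)

    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]

    n_mut = int(round(cfg.mutant_prevalence * n))
    n_wt = n - n_mut
    n_mutlike = int(round(cfg.mutlike_fraction * n_wt))

    order = rng.permutation(n)
    mut_idx = order[:n_mut]
    mutlike_idx = order[n_mut : n_mut + n_mutlike]

    true_mutant = np.zeros(n, dtype=bool)
    true_mutant[mut_idx] = True
    true_mutlike = np.zeros(n, dtype=bool)
    true_mutlike[mutlike_idx] = True

    activation = rng.beta(1.0, 10.0, size=n)  # background noise
    activation[true_mutant | true_mutlike] = 1.0

    # counts: NB around 2^(baseline + delta * activation) for program genes
    lo, hi = cfg.baseline_log_mean_range
    baseline_log = rng_bio.uniform(lo, hi, size=cfg.n_genes)
    program = np.zeros(cfg.n_genes, dtype=bool)
    program[rng_bio.choice(cfg.n_genes, size=cfg.n_program_genes, replace=False)] = True
    log_mean = np.tile(baseline_log[:, None], (1, n))
    log_mean[program, :] += cfg.effect_size_delta * activation[None, :]
    counts = _negative_binomial(rng, np.exp2(log_mean), cfg.dispersion)
    expr = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=gene_ids, columns=sample_ids),
        stage="counts",
    )

    # survival: exponential event times, independent exponential censoring
    hazard = cfg.baseline_hazard * np.exp(cfg.hazard_coef_gamma * activation)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        censor_hazard = cfg.baseline_hazard * cfg.censor_rate / (1 - cfg.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_days = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    # clinical covariates: blasts and WBC decrease with activation
    blast_pct = np.clip(rng.normal(70 - 25 * activation, 12), 1.0, 100.0)
    wbc = np.clip(rng.normal(35 - 15 * activation, 12), 0.5, None)

    disease_stage = rng.choice(
        ["diagnostic", "relapse", "residual"], size=n, p=[0.7, 0.15, 0.15]
    )
    eln = np.where(
        activation > 0.5,
        rng.choice(["favorable", "intermediate", "adverse"], size=n, p=[0.1, 0.2, 0.7]),
        rng.choice(["favorable", "intermediate", "adverse"], size=n, p=[0.35, 0.4, 0.25]),
    )
    allelic = np.full(n, "none", dtype=object)
    allelic[true_mutant] = rng.choice(["biallelic", "monoallelic"], size=n_mut, p=[0.8, 0.2])

    ann = pd.DataFrame(
        {
            "tp53_status": np.where(true_mutant, "MUT", "WT"),
            "disease_stage": disease_stage,
            "os_days": os_days,
            "os_event": os_event,
            "blast_pct": blast_pct,
            "wbc": wbc,
            "eln2022": eln,
            "allelic": allelic,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # drug AUC: baseline per drug + resistance shift with activation + noise
    drug_ids = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    drug_baseline = rng_bio.uniform(80, 220, size=cfg.n_drugs)
    auc = (
        drug_baseline[:, None]
        + cfg.drug_resistance_coef * activation[None, :]
        + rng.normal(0, 10, size=(cfg.n_drugs, n))
    )
    drugs = pd.DataFrame(auc, index=drug_ids, columns=sample_ids)

    truth = SyntheticTruth(
        program_gene_ids=[g for g, f in zip(gene_ids, program) if f],
        table=pd.DataFrame(
            {
                "activation": activation,
                "true_mutant": true_mutant,
                "true_mutlike": true_mutlike,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    return expr, ann, drugs, truth


def write_cohort(
    outdir: str | Path,
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    drugs: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the cohort bundle as TSVs that round-trip through :mod:`mutlike.io`."""
    if expr.shape[1] == 0:
        raise ValueError("refusing to write a cohort with zero samples")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "drugs": outdir / "drug_auc.tsv",
        "truth": outdir / "truth.tsv",
        "program_genes": outdir / "program_genes.txt",
    }
    write_expression(expr, paths["expression"])
    write_annotation(ann, paths["annotation"])
    d = drugs.copy()
    d.index.name = "drug_id"
    d.to_csv(paths["drugs"], sep="\t", lineterminator="\n", float_format="%.10g")
    t = truth.table.copy()
    t["true_mutant"] = t["true_mutant"].astype(int)
    t["true_mutlike"] = t["true_mutlike"].astype(int)
    t.reset_index().to_csv(
        paths["truth"], sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )
    paths["program_genes"].write_text("\n".join(truth.program_gene_ids) + "\n")
    return paths
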