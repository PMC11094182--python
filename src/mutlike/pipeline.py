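"""Derivation of the mutant-like expression subtype.

The procedure mirrors the study design it implements:

1. split the cohort 60/40 (stratified on mutation status) and train a
   ridge-penalized logistic classifier of mutant vs rest on the
   training split;
2. score every sample; among *wild-type* samples, call the top decile
   of ridge scores the mutant-like (``MUTLIKE``) class;
3. train a complementary ridge model of MUTLIKE vs WT on wild-type
   samples only (mutants are excluded by a hard guard) so the class can
   be transferred to cohorts with their own mutants held out;
4. transfer the frozen complementary model to a second cohort and
   re-apply the decile rule within that cohort's wild-type samples;
5. distil a compact core signature by repeated elastic-net fits on
   stratified bootstrap resamples, keeping the k most recurrently
   selected genes, and refit a ridge model on those genes alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import io as gio
from .glm import (
    DEFAULT_LAMBDA_GRID,
    PenalizedModel,
    evaluate_classifier,
    fit_penalized_logistic,
    score_samples,
    select_lambda_cv,
)
from .io import ExpressionMatrix
from .survival import pairwise_survival
from .stats import compare_table, drug_auc_zscores


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels with the score threshold that minted them."""

    table: pd.DataFrame  # index sample_id; columns group, ridge_score
    threshold_used: float

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def counts(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


@dataclass
class SignatureReport:
    selection_count: pd.Series  # per gene, over n_iter iterations
    core_genes: list[str]
    n_iter: int
    k: int


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    k = max(1, math.ceil(q * v.size))
    return float(v[k - 1])


def derive_mutlike_labels(
    scores: pd.DataFrame, ann: pd.DataFrame, decile: float = 0.10
) -> SubtypeAssignment:
    """Label wild-type samples above the (1 - decile) score quantile MUTLIKE.

    The threshold is the nearest-rank (1 - decile)-quantile of the
    wild-type ridge scores; membership is strict (score > threshold), so
    fully tied scores yield no MUTLIKE calls. Mutants keep the MUT label
    regardless of score.
    """
    if not 0 < decile < 1:
        raise ValueError("decile must lie in (0, 1)")
    wt = ann.index[ann["tp53_status"] == "WT"]
    missing = wt.difference(scores.index)
    if len(missing):
        raise ValueError(f"scores missing for wild-type samples: {list(missing)[:5]}")
    if len(wt) < 10:
        raise ValueError("need at least 10 wild-type samples for a decile rule")
    wt_scores = scores.loc[wt, "ridge_score"].to_numpy()
    q90 = _nearest_rank_quantile(wt_scores, 1.0 - decile)
    shared = ann.index.intersection(scores.index)
    group = pd.Series("WT", index=shared, name="group")
    group[ann.loc[shared, "tp53_status"] == "MUT"] = "MUT"
    is_wt = group == "WT"
    group[is_wt & (scores.loc[shared, "ridge_score"] > q90)] = "MUTLIKE"
    table = pd.DataFrame(
        {"group": group, "ridge_score": scores.loc[shared, "ridge_score"]}
    )
    table.index.name = "sample_id"
    return SubtypeAssignment(table=table, threshold_used=q90)


def train_complementary_model(
    X: ExpressionMatrix,
    ann: pd.DataFrame,
    assignment: SubtypeAssignment,
    train_fraction: float = 0.6,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[PenalizedModel, dict[str, float]]:
    """Ridge model of MUTLIKE vs WT fitted on wild-type samples only.

    ``X`` must already be restricted to wild-type samples — any mutant
    sample in the matrix is an error, which guarantees mutants can never
    leak into this fit. Returns the model plus held-out metrics.
    """
    mut_in_X = [s for s in X.sample_ids if ann.loc[s, "tp53_status"] == "MUT"]
    if mut_in_X:
        raise ValueError(
            f"mutant samples present in complementary training matrix: {mut_in_X[:5]}"
        )
    y = (assignment.groups.reindex(X.sample_ids) == "MUTLIKE").astype(float)
    wt_ann = ann.loc[X.sample_ids].copy()
    wt_ann["_mutlike"] = np.where(y.to_numpy() == 1, "MUTLIKE", "WT")
    train_ids, test_ids = gio.split_train_test(
        wt_ann, train_fraction, seed=seed, stratify_by="_mutlike"
    )
    Xtr = ExpressionMatrix(X.values[train_ids], stage=X.stage)
    lam, _ = select_lambda_cv(
        Xtr, y[train_ids], lambda_grid, alpha=0.0, n_folds=n_folds, seed=seed
    )
    model = fit_penalized_logistic(Xtr, y[train_ids], lam, alpha=0.0)
    Xte = ExpressionMatrix(X.values[test_ids], stage=X.stage)
    metrics = evaluate_classifier(score_samples(model, Xte), y[test_ids])
    metrics["lambda"] = lam
    # refit on all wild-type samples so the transferable model uses every case
    model = fit_penalized_logistic(X, y, lam, alpha=0.0)
    return model, metrics


def transfer_model(
    model: PenalizedModel,
    X2: ExpressionMatrix,
    ann2: pd.DataFrame,
    decile: float = 0.10,
    threshold: float | None = None,
) -> SubtypeAssignment:
    """Apply a frozen model to a second cohort and re-derive labels there.

    By default the decile threshold is recomputed within the target
    cohort's wild-type scores; pass ``threshold`` to reuse an absolute
    score cutoff instead.
    """
    if (ann2["tp53_status"] == "WT").sum() == 0:
        raise ValueError("target cohort has no wild-type samples")
    scores = score_samples(model, X2)  # raises if genes are not harmonized
    if threshold is None:
        return derive_mutlike_labels(scores, ann2, decile)
    shared = ann2.index.intersection(scores.index)
    group = pd.Series("WT", index=shared, name="group")
    group[ann2.loc[shared, "tp53_status"] == "MUT"] = "MUT"
    sel = (group == "WT") & (scores.loc[shared, "ridge_score"] > threshold)
    group[sel] = "MUTLIKE"
    table = pd.DataFrame({"group": group, "ridge_score": scores.loc[shared, "ridge_score"]})
    table.index.name = "sample_id"
    return SubtypeAssignment(table=table, threshold_used=threshold)


def derive_core_signature(
    X: ExpressionMatrix,
    y: pd.Series,
    n_iter: int = 100,
    k: int = 25,
    alpha: float = 0.5,
    seed: int = 0,
    lambda_grid: tuple[float, ...] = (0.001, 0.01, 0.1),
    n_folds: int = 3,
    cv_per_iteration: bool = False,
) -> SignatureReport:
    """Stability-selected core gene signature from repeated elastic nets.

    Each iteration draws a stratified bootstrap of samples, fits an
    elastic-net logistic model and records the genes with nonzero
    coefficients; the core signature is the ``k`` genes with the highest
    selection count (ties broken lexicographically). The elastic-net
    penalty is CV-selected once on the full data and reused across
    iterations; ``cv_per_iteration`` re-selects it inside every
    bootstrap instead.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if isinstance(y, pd.Series):
        y = y.reindex(X.sample_ids)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    lam = None
    if not cv_per_iteration:
        lam, _ = select_lambda_cv(
            X, yv, lambda_grid, alpha=alpha, n_folds=n_folds, seed=seed,
            tol=1e-4, max_iter=2000,
        )
    pos_idx = np.flatnonzero(yv == 1)
    neg_idx = np.flatnonzero(yv == 0)
    counts = pd.Series(0, index=pd.Index(X.gene_ids, name="gene_id"), dtype=int)
    for _ in range(n_iter):
        boot = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        Xb = ExpressionMatrix(
            X.values.iloc[:, boot].set_axis(
                [f"b{i}" for i in range(boot.size)], axis=1
            ),
            stage=X.stage,
        )
        yb = yv[boot]
        lam_it = lam
        if cv_per_iteration:
            lam_it, _ = select_lambda_cv(
                Xb, yb, lambda_grid, alpha=alpha, n_folds=n_folds,
                seed=int(rng.integers(2**31)), tol=1e-4, max_iter=2000,
            )
        m = fit_penalized_logistic(Xb, yb, lam_it, alpha=alpha, tol=1e-4, max_iter=2000)
        counts[np.abs(m.beta) > 0] += 1
    ever = counts[counts > 0]
    if k > len(ever):
        warnings.warn(
            f"only {len(ever)} genes ever selected; returning all of them"
        )
        k_eff = len(ever)
    else:
        k_eff = k
    ranked = sorted(ever.index, key=lambda g: (-ever[g], g))
    return SignatureReport(
        selection_count=counts, core_genes=ranked[:k_eff], n_iter=n_iter, k=k
    )


def refit_signature_model(
    X: ExpressionMatrix,
    y: pd.Series,
    core_genes: list[str],
    train_fraction: float = 0.6,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> tuple[PenalizedModel, dict[str, float]]:
    """Ridge model restricted to the core signature genes, with held-out
    evaluation."""
    if not core_genes:
        raise ValueError("core gene list is empty")
    missing = [g for g in core_genes if g not in X.values.index]
    if missing:
        raise ValueError(f"core genes absent from matrix: {missing}")
    sub = ExpressionMatrix(X.values.loc[core_genes], stage=X.stage)
    y = y.reindex(X.sample_ids)
    strat = pd.DataFrame(
        {"_y": np.where(y.to_numpy() == 1, "pos", "neg")}, index=y.index
    )
    train_ids, test_ids = gio.split_train_test(
        strat, train_fraction, seed=seed, stratify_by="_y"
    )
    Xtr = ExpressionMatrix(sub.values[train_ids], stage=sub.stage)
    lam, _ = select_lambda_cv(Xtr, y[train_ids], lambda_grid, alpha=0.0, seed=seed)
    model = fit_penalized_logistic(Xtr, y[train_ids], lam, alpha=0.0)
    Xte = ExpressionMatrix(sub.values[test_ids], stage=sub.stage)
    metrics = evaluate_classifier(score_samples(model, Xte), y[test_ids])
    metrics["lambda"] = lam
    return model, metrics


def _oof_scores(
    X: ExpressionMatrix,
    y: np.ndarray,
    lam: float,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold ridge scores: each sample scored by a model that never
    saw it (optional, pessimistic alternative to whole-cohort scoring)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    A = X.values.to_numpy().T
    score = np.empty(A.shape[0])
    for tr, te in skf.split(A, y):
        Xtr = ExpressionMatrix(X.values.iloc[:, tr], stage=X.stage)
        m = fit_penalized_logistic(Xtr, y[tr], lam, alpha=0.0)
        score[te] = m.beta0 + A[te] @ m.beta
    return pd.DataFrame(
        {"ridge_score": score, "probability": 1 / (1 + np.exp(-score))},
        index=pd.Index(X.sample_ids, name="sample_id"),
    )


@dataclass
class PipelineConfig:
    train_fraction: float = 0.6
    decile: float = 0.10
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_folds: int = 5
    signature_alpha: float = 0.5
    signature_n_iter: int = 100
    signature_k: int = 25
    signature_lambda_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    out_of_fold_scores: bool = False
    seed: int = 0


def load_cohort(
    cohort_dir: str | Path,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame | None]:
    """Read an (expression, annotation[, drug]) cohort bundle from a directory."""
    d = Path(cohort_dir)
    expr = gio.read_expression(d / "expression.tsv")
    ann = gio.read_annotation(d / "annotation.tsv")
    drug_path = d / "drug_auc.tsv"
    drugs = None
    if drug_path.exists():
        drugs = pd.read_csv(drug_path, sep="\t", index_col=0)
        drugs.columns = drugs.columns.astype(str)
    return expr, ann, drugs


def run_full_pipeline(
    exprA: ExpressionMatrix,
    annA: pd.DataFrame,
    exprB: ExpressionMatrix | None = None,
    annB: pd.DataFrame | None = None,
    drugsA: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the whole subtype-derivation analysis on one or two cohorts.

    Returns a report dict with the fitted models, subtype assignments,
    held-out metrics, survival tables, clinical/drug comparisons and the
    core signature. When ``outdir`` is given the main artifacts plus a
    run manifest are written as TSV/JSON.
    """
    cfg = config or PipelineConfig()
    report: dict = {"config": asdict(cfg)}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("normalize"):
        zA = gio.normalize(exprA)
        log2A = gio.log2cpm(gio.cpm(exprA))

    with stage("split+fit"):
        train_ids, test_ids = gio.split_train_test(
            annA, cfg.train_fraction, seed=cfg.seed
        )
        y_mut = (annA["tp53_status"] == "MUT").astype(float)
        Xtr = ExpressionMatrix(zA.values[train_ids], stage="zscore")
        lam, cv_table = select_lambda_cv(
            Xtr, y_mut[train_ids], cfg.lambda_grid, alpha=0.0,
            n_folds=cfg.n_folds, seed=cfg.seed,
        )
        mut_model = fit_penalized_logistic(Xtr, y_mut[train_ids], lam, alpha=0.0)
        Xte = ExpressionMatrix(zA.values[test_ids], stage="zscore")
        report["mut_classifier_metrics"] = evaluate_classifier(
            score_samples(mut_model, Xte), y_mut[test_ids]
        )
        report["mut_classifier_lambda"] = lam
        report["mut_model"] = mut_model

    with stage("derive_mutlike"):
        if cfg.out_of_fold_scores:
            scoresA = _oof_scores(
                zA, y_mut.to_numpy(), lam, n_folds=cfg.n_folds, seed=cfg.seed
            )
        else:
            scoresA = score_samples(mut_model, zA)
        assignA = derive_mutlike_labels(scoresA, annA, cfg.decile)
        report["assignment_A"] = assignA
        annA = annA.copy()
        annA["group"] = assignA.groups.reindex(annA.index)

    with stage("complementary_model"):
        wt_ids = annA.index[annA["tp53_status"] == "WT"].tolist()
        Xwt = ExpressionMatrix(zA.values[wt_ids], stage="zscore")
        comp_model, comp_metrics = train_complementary_model(
            Xwt, annA, assignA,
            train_fraction=cfg.train_fraction,
            lambda_grid=cfg.lambda_grid,
            n_folds=cfg.n_folds,
            seed=cfg.seed,
        )
        report["complementary_model"] = comp_model
        report["complementary_metrics"] = comp_metrics

    if exprB is not None and annB is not None:
        with stage("transfer"):
            zB = gio.normalize(exprB)
            zB_h = ExpressionMatrix(
                zB.values.reindex(comp_model.gene_ids).dropna(), stage="zscore"
            )
            assignB = transfer_model(comp_model, zB_h, annB, decile=cfg.decile)
            report["assignment_B"] = assignB
            annB = annB.copy()
            annB["group"] = assignB.groups.reindex(annB.index)
            report["annB"] = annB
    else:
        report["transfer_skipped"] = "no second cohort supplied"

    with stage("signature"):
        y_ml = (assignA.groups.reindex(wt_ids) == "MUTLIKE").astype(float)
        sig = derive_core_signature(
            Xwt, y_ml,
            n_iter=cfg.signature_n_iter,
            k=cfg.signature_k,
            alpha=cfg.signature_alpha,
            seed=cfg.seed,
            lambda_grid=cfg.signature_lambda_grid,
        )
        report["signature"] = sig
        sig_model, sig_metrics = refit_signature_model(
            Xwt, y_ml, sig.core_genes,
            train_fraction=cfg.train_fraction,
            seed=cfg.seed,
        )
        report["signature_model"] = sig_model
        report["signature_metrics"] = sig_metrics

    with stage("survival"):
        medians, pairwise = pairwise_survival(annA)
        report["survival_medians"] = medians
        report["survival_pairwise"] = pairwise

    with stage("clinical"):
        clin = annA[["blast_pct", "wbc"]].T
        comp_rows = {}
        for pair in (("MUT", "WT"), ("MUTLIKE", "WT")):
            comp_rows["{}_vs_{}".format(*pair)] = compare_table(
                clin, annA["group"], pair
            )
        report["clinical_comparisons"] = comp_rows

    if drugsA is not None:
        with stage("drugs"):
            aucz = drug_auc_zscores(drugsA)
            drug_rows = {}
            for pair in (("MUT", "WT"), ("MUTLIKE", "WT")):
                drug_rows["{}_vs_{}".format(*pair)] = compare_table(
                    aucz, annA["group"], pair
                )
            report["drug_comparisons"] = drug_rows
            report["drug_aucz"] = aucz

    report["annA"] = annA
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report["assignment_A"].table.reset_index().to_csv(
        outdir / "assignment_A.tsv", sep="\t", index=False, lineterminator="\n"
    )
    if "assignment_B" in report:
        report["assignment_B"].table.reset_index().to_csv(
            outdir / "assignment_B.tsv", sep="\t", index=False, lineterminator="\n"
        )
    report["mut_model"].to_json(outdir / "mut_model.json")
    report["complementary_model"].to_json(outdir / "complementary_model.json")
    report["signature_model"].to_json(outdir / "signature_model.json")
    sig = report["signature"]
    sig.selection_count.rename("selection_count").reset_index().to_csv(
        outdir / "signature_counts.tsv", sep="\t", index=False, lineterminator="\n"
    )
    (outdir / "core_genes.txt").write_text("\n".join(sig.core_genes) + "\n")
    report["survival_medians"].to_csv(
        outdir / "survival_medians.tsv", sep="\t", index=False, lineterminator="\n"
    )
    report["survival_pairwise"].to_csv(
        outdir / "survival_pairwise.tsv", sep="\t", index=False, lineterminator="\n"
    )
    import sklearn

    manifest = {
        "config": report["config"],
        "metrics": {
            "mut_classifier": report["mut_classifier_metrics"],
            "complementary": report["complementary_metrics"],
            "signature": report["signature_metrics"],
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
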