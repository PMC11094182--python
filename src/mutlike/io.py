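"""Reading, writing and normalizing expression cohorts.

The on-disk layout is plain TSV throughout: expression matrices are
genes x samples with a header row of sample ids and gene ids in the
first column; annotation, drug-response and truth tables are one row
per record. Gene sets use the standard GMT layout (set name,
description, then tab-separated gene ids).

Expression values move through four declared stages:

    counts -> cpm -> log2cpm -> zscore

``normalize`` performs the full chain used by every downstream model:
counts-per-million, log2(CPM + 1), then a per-gene z-score across
samples (sample standard deviation, n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STAGES = ("counts", "cpm", "log2cpm", "zscore")

ANNOTATION_COLUMNS = [
    "sample_id",
    "tp53_status",
    "disease_stage",
    "os_days",
    "os_event",
    "blast_pct",
    "wbc",
    "eln2022",
    "allelic",
]


class ParseError(ValueError):
    """A file violated the declared TSV layout."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared processing stage."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    stage: str = "counts"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dupes}")
        if self.stage == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts stage must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression(path: str | Path, stage: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV; ids keep file order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ParseError(f"{path.name}: non-numeric values in columns {bad.tolist()}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path.name}: missing/ragged values in rows {rows}")
    return ExpressionMatrix(df.astype(float), stage=stage)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Per-sample clinical table; index = sample_id."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"annotation missing columns {missing}")
    if ann["sample_id"].duplicated().any():
        raise ParseError("duplicate sample ids in annotation")
    ann = ann.set_index("sample_id")
    if (ann["os_days"] < 0).any():
        raise ParseError("negative os_days in annotation")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.reset_index() if ann.index.name == "sample_id" else ann
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets: one per line as ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"GMT line {ln}: fewer than 3 fields")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ParseError(f"GMT line {ln}: duplicate set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain one-gene-per-line list (e.g. surface-marker annotation)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.stage != "counts":
        raise ValueError(f"cpm expects counts, got {m.stage}")
    libsize = m.values.sum(axis=0)
    zero = libsize.index[libsize <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size for samples {zero}")
    return ExpressionMatrix(m.values / libsize * 1e6, stage="cpm")


def log2cpm(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if m.stage == "counts":
        m = cpm(m)
    if m.stage != "cpm":
        raise ValueError(f"log2cpm expects counts or cpm, got {m.stage}")
    return ExpressionMatrix(np.log2(m.values + pseudocount), stage="log2cpm")


def zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z across samples; sd-zero genes map to an all-zero row."""
    if m.stage not in ("log2cpm", "zscore"):
        raise ValueError(f"zscore expects log2cpm (or zscore), got {m.stage}")
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    z = m.values.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return ExpressionMatrix(z, stage="zscore")


def normalize(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """counts -> CPM -> log2(CPM + pseudocount) -> per-gene z-score."""
    if m.stage != "counts":
        raise ValueError(f"normalize expects counts, got {m.stage}")
    return zscore(log2cpm(cpm(m)))


def harmonize_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared gene set, sorted lexicographically."""
    if a.stage != b.stage:
        raise ValueError(f"stage mismatch: {a.stage} vs {b.stage}")
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("no shared genes between matrices")
    return (
        ExpressionMatrix(a.values.loc[shared], stage=a.stage),
        ExpressionMatrix(b.values.loc[shared], stage=b.stage),
    )


def split_train_test(
    ann: pd.DataFrame,
    train_fraction: float = 0.6,
    seed: int = 0,
    stratify_by: str | None = "tp53_status",
) -> tuple[list[str], list[str]]:
    """Stratified sample partition, reproducible under ``seed``.

    Stratification (default on mutation status) keeps the minority mutant
    class represented on both sides; pass ``stratify_by=None`` for a plain
    random split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    samples = ann.index.to_numpy()
    if stratify_by is None:
        strata = [samples]
    else:
        strata = [
            samples[(ann[stratify_by] == v).to_numpy()]
            for v in sorted(ann[stratify_by].unique())
        ]
    train: list[str] = []
    test: list[str] = []
    for group in strata:
        group = np.sort(group)
        perm = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        train.extend(group[perm[:n_train]])
        test.extend(group[perm[n_train:]])
    return sorted(train), sorted(test)
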