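"""Group comparisons, drug-response z-scoring, FDR control and PCA.

Clinical and drug comparisons use the unpaired two-sample t-test
(pooled variance by default, Welch by flag) with Benjamini-Hochberg
adjustment applied per explicit family. Drug AUC values are z-scored
per drug across samples and sign-flipped so that a high z means drug
*sensitivity* (low area under the ex-vivo dose-response curve).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


def drug_auc_zscores(auc: pd.DataFrame) -> pd.DataFrame:
    """Per-drug z-score over non-missing samples, multiplied by -1.

    Rows are drugs, columns samples. Rows with fewer than two non-missing
    values are set entirely missing (with a warning); missing entries
    stay missing.
    """
    out = auc.copy().astype(float)
    for drug, row in out.iterrows():
        obs = row.dropna()
        if len(obs) < 2:
            warnings.warn(f"drug {drug}: <2 observed AUC values; row set missing")
            out.loc[drug] = np.nan
            continue
        sd = obs.std(ddof=1)
        if sd == 0:
            out.loc[drug] = (row - obs.mean()) * 0.0
        else:
            out.loc[drug] = -(row - obs.mean()) / sd
    return out


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    group_pair: tuple[str, str],
    equal_var: bool = True,
) -> dict[str, float]:
    """Unpaired two-sample t-test of ``group_pair[0]`` vs ``group_pair[1]``.

    Missing values are dropped pairwise. Two constant equal groups give
    t = 0, p = 1 rather than NaN.
    """
    g1, g2 = group_pair
    a = values[groups == g1].dropna().to_numpy(dtype=float)
    b = values[groups == g2].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(a.mean() - b.mean()) * np.inf, 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {
        "group1_mean": float(a.mean()),
        "group2_mean": float(b.mean()),
        "group1_sem": float(sps.sem(a)) if len(a) > 1 else float("nan"),
        "group2_sem": float(sps.sem(b)) if len(b) > 1 else float("nan"),
        "t": float(t),
        "p": float(p),
        "n1": float(len(a)),
        "n2": float(len(b)),
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR: fdr_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.clip(fdr_sorted, 0, 1)
    return fdr


def compare_table(
    data: pd.DataFrame,
    groups: pd.Series,
    group_pair: tuple[str, str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """One t-test per row of ``data`` (variables x samples), BH-adjusted
    across the rows as one family."""
    rows = []
    for var in data.index:
        res = compare_groups(data.loc[var], groups, group_pair, equal_var=equal_var)
        res["variable"] = var
        rows.append(res)
    table = pd.DataFrame(rows).set_index("variable")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def project_pca(
    X: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Descriptive PCA of samples over the gene space.

    Returns per-sample coordinates on the top components and the
    variance-explained fractions.
    """
    A = X.values.to_numpy().T  # samples x genes
    if n_components > min(A.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.allclose(A, A.mean(axis=0), atol=1e-12):
        raise ValueError("matrix has no variance to project")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(A)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=pd.Index(X.sample_ids, name="sample_id"), columns=cols),
        pca.explained_variance_ratio_.copy(),
    )
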