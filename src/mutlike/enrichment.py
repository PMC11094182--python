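"""Gene ranking, preranked gene-set enrichment and marker overlap.

Preranked GSEA follows the published convention (Subramanian et al.,
PNAS 2005): for a gene list ranked by statistic r_g (descending) and a
set S of m genes among N,

    P_hit(i)  = sum_{g in S, rank(g) <= i} |r_g|^p / sum_{g in S} |r_g|^p
    P_miss(i) = (number of non-members with rank <= i) / (N - m)

and the enrichment score ES is the maximum-magnitude deviation of
P_hit - P_miss. With weight p = 0 this reduces to the classic
Kolmogorov-Smirnov running sum (equal hit increments 1/m). The null is
built from gene-label permutations (random size-m sets); NES divides ES
by the mean magnitude of same-sign null ES values, the nominal p is the
same-sign null tail fraction, and the FDR compares each NES against the
null NES values pooled over all sets, separately by sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .stats import bh_adjust


@dataclass
class RankedList:
    """Genes ordered by ranking statistic, descending; ties broken by id."""

    gene_ids: list[str]
    statistic: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.statistic):
            raise ValueError("gene_ids and statistic length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")


def rank_genes(
    X: ExpressionMatrix, groups: pd.Series, group_pair: tuple[str, str]
) -> RankedList:
    """Per-gene Welch t statistic of ``group_pair[0]`` vs ``group_pair[1]``.

    ``X`` is expected at the log2cpm stage. Genes with zero variance in
    both groups get statistic 0.
    """
    g1, g2 = group_pair
    s1 = [s for s in X.sample_ids if groups.get(s) == g1]
    s2 = [s for s in X.sample_ids if groups.get(s) == g2]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("need at least 3 samples per group to rank genes")
    a = X.values[s1].to_numpy()
    b = X.values[s2].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.nan_to_num(np.asarray(t, dtype=float), nan=0.0)
    order = sorted(range(len(t)), key=lambda i: (-t[i], X.gene_ids[i]))
    return RankedList(
        gene_ids=[X.gene_ids[i] for i in order], statistic=t[np.array(order)]
    )


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list[str] = field(default_factory=list)


def _running_es(hit_pos: np.ndarray, weights: np.ndarray, n_genes: int) -> tuple[float, int]:
    """ES and the 0-based rank position of the extreme deviation.

    ``hit_pos`` are sorted 0-based ranks of the set members; ``weights``
    is |r|^p over the whole ranked list.
    """
    m = hit_pos.size
    w = weights[hit_pos]
    total = w.sum()
    n_miss = n_genes - m
    if total == 0 or n_miss == 0:
        return 0.0, int(hit_pos[0]) if m else 0
    hit_cum = np.cumsum(w) / total
    k = np.arange(1, m + 1)
    miss_after = (hit_pos + 1 - k) / n_miss  # misses seen once hit k processed
    after = hit_cum - miss_after  # candidates for the positive extreme
    before = np.concatenate(([0.0], hit_cum[:-1])) - (hit_pos - (k - 1)) / n_miss
    i_after = int(np.argmax(np.abs(after)))
    i_before = int(np.argmax(np.abs(before)))
    if np.abs(after[i_after]) >= np.abs(before[i_before]):
        return float(after[i_after]), int(hit_pos[i_after])
    return float(before[i_before]), int(hit_pos[i_before]) - 1


def _null_es(
    rng: np.random.Generator,
    m: int,
    weights: np.ndarray,
    n_genes: int,
    n_perm: int,
) -> np.ndarray:
    """ES values for ``n_perm`` random size-m sets (gene-label null)."""
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n_genes, size=m, replace=False))
        out[i], _ = _running_es(pos, weights, n_genes)
    return out


def gsea_preranked(
    ranked: RankedList,
    sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA over ``sets`` with a gene-label permutation null.

    Returns one row per retained set with ES, NES, nominal p, FDR, size
    and the leading-edge genes (comma-joined). Sets smaller than
    ``min_size`` after intersection with the list are skipped; a set
    must also leave at least one non-member.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked.gene_ids)
    pos_of = {g: i for i, g in enumerate(ranked.gene_ids)}
    weights = np.abs(ranked.statistic) ** weight

    kept: list[tuple[str, np.ndarray]] = []
    for name, genes in sets.items():
        hit = np.sort(np.array([pos_of[g] for g in set(genes) if g in pos_of], dtype=int))
        if hit.size == 0:
            warnings.warn(f"gene set {name!r} absent from ranked list; skipped")
            continue
        if hit.size < min_size:
            warnings.warn(f"gene set {name!r} below min_size {min_size}; skipped")
            continue
        if hit.size >= n:
            raise ValueError(f"gene set {name!r} covers the whole list")
        kept.append((name, hit))

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, hit in kept:
        es, peak = _running_es(hit, weights, n)
        null = _null_es(rng, hit.size, weights, n, n_perm)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            p = float((same >= es).mean()) if same.size else 1.0 / n_perm
            denom = same.mean() if same.size else np.nan
        else:
            same = neg_null
            p = float((same <= es).mean()) if same.size else 1.0 / n_perm
            denom = np.abs(same).mean() if same.size else np.nan
        nes = float(es / denom) if denom and np.isfinite(denom) and denom > 0 else 0.0
        # normalize this set's null the same way, for the pooled FDR null
        null_nes = np.zeros_like(null)
        if pos_null.size:
            null_nes[null >= 0] = null[null >= 0] / pos_null.mean()
        if neg_null.size:
            null_nes[null < 0] = null[null < 0] / np.abs(neg_null).mean()
        null_nes_pool.append(null_nes)
        if es >= 0:
            le = [ranked.gene_ids[i] for i in hit if i <= peak]
        else:
            le = [ranked.gene_ids[i] for i in hit if i > peak]
        rows.append(
            {"set": name, "es": es, "nes": nes, "p": max(p, 0.0), "size": hit.size,
             "leading_edge": ",".join(le)}
        )

    res = pd.DataFrame(rows)
    if res.empty:
        return res
    pool = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    pool_pos, obs_pos = pool[pool >= 0], obs[obs >= 0]
    pool_neg, obs_neg = pool[pool < 0], obs[obs < 0]
    for i, nes in enumerate(obs):
        if nes >= 0:
            num = (pool_pos >= nes).mean() if pool_pos.size else 0.0
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            num = (pool_neg <= nes).mean() if pool_neg.size else 0.0
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    res["fdr"] = fdr
    return res.set_index("set")[["es", "nes", "p", "fdr", "size", "leading_edge"]]


def gsea_phenotype(
    X: ExpressionMatrix,
    groups: pd.Series,
    group_pair: tuple[str, str],
    sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 200,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """GSEA with a phenotype-permutation null.

    Group labels are shuffled among the compared samples and the whole
    ranking is recomputed for each permutation, which preserves
    inter-gene correlation in the null at the cost of ``n_perm`` full
    re-rankings. Output columns match :func:`gsea_preranked` except that
    FDR is a BH adjustment of the nominal p values (the pooled-null
    convention is kept for the preranked default path).
    """
    rng = np.random.default_rng(seed)
    observed = rank_genes(X, groups, group_pair)
    n = len(observed.gene_ids)
    weights = np.abs(observed.statistic) ** weight
    pos_of = {g: i for i, g in enumerate(observed.gene_ids)}

    kept: list[tuple[str, set[str]]] = []
    for name, genes in sets.items():
        present = {g for g in genes if g in pos_of}
        if min_size <= len(present) < n:
            kept.append((name, present))
        else:
            warnings.warn(f"gene set {name!r} skipped (size {len(present)})")
    if not kept:
        return pd.DataFrame()

    es_obs = {}
    for name, present in kept:
        hit = np.sort(np.array([pos_of[g] for g in present]))
        es_obs[name] = _running_es(hit, weights, n)[0]

    labels = groups.reindex(X.sample_ids)
    in_pair = labels.isin(group_pair).to_numpy()
    null = {name: np.empty(n_perm) for name, _ in kept}
    for b in range(n_perm):
        perm = labels.copy()
        vals = perm.to_numpy(copy=True)
        vals[in_pair] = rng.permutation(vals[in_pair])
        perm = pd.Series(vals, index=perm.index)
        rl = rank_genes(X, perm, group_pair)
        w = np.abs(rl.statistic) ** weight
        ppos = {g: i for i, g in enumerate(rl.gene_ids)}
        for name, present in kept:
            hit = np.sort(np.array([ppos[g] for g in present]))
            null[name][b], _ = _running_es(hit, w, n)

    rows = []
    for name, present in kept:
        es = es_obs[name]
        nl = null[name]
        same = nl[nl >= 0] if es >= 0 else nl[nl < 0]
        if es >= 0:
            p = float((same >= es).mean()) if same.size else 1.0 / n_perm
        else:
            p = float((same <= es).mean()) if same.size else 1.0 / n_perm
        denom = np.abs(same).mean() if same.size else np.nan
        nes = float(es / denom) if denom and np.isfinite(denom) and denom > 0 else 0.0
        rows.append({"set": name, "es": es, "nes": nes, "p": p, "size": len(present)})
    res = pd.DataFrame(rows).set_index("set")
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res


def concordance_filter(
    res_a: pd.DataFrame, res_b: pd.DataFrame, fdr_cut: float = 0.05
) -> list[str]:
    """Sets significant in both cohorts with same-sign NES."""
    shared = res_a.index.intersection(res_b.index)
    keep = []
    for s in shared:
        if (
            np.sign(res_a.loc[s, "nes"]) == np.sign(res_b.loc[s, "nes"])
            and res_a.loc[s, "fdr"] < fdr_cut
            and res_b.loc[s, "fdr"] < fdr_cut
        ):
            keep.append(s)
    return keep


@dataclass
class MarkerOverlap:
    per_comparison: dict[str, pd.DataFrame]  # marker genes significant+concordant per comparison
    intersection: pd.DataFrame  # markers shared across comparisons with agreeing direction


def _concordant_markers(
    de_a: pd.DataFrame, de_b: pd.DataFrame, markers: list[str], fdr_cut: float
) -> pd.DataFrame:
    """Markers with fdr < cut in both cohorts and the same direction.

    ``de_a``/``de_b`` are per-gene tables indexed by gene with columns
    ``t`` (signed statistic) and ``fdr``.
    """
    rows = []
    for g in markers:
        if g not in de_a.index or g not in de_b.index:
            continue
        ta, tb = de_a.loc[g, "t"], de_b.loc[g, "t"]
        if (
            de_a.loc[g, "fdr"] < fdr_cut
            and de_b.loc[g, "fdr"] < fdr_cut
            and np.sign(ta) == np.sign(tb)
            and np.sign(ta) != 0
        ):
            rows.append({"gene": g, "direction": "up" if ta > 0 else "down"})
    return pd.DataFrame(rows, columns=["gene", "direction"]).set_index("gene")


def surface_marker_overlap(
    de_mut: tuple[pd.DataFrame, pd.DataFrame],
    de_mutlike: tuple[pd.DataFrame, pd.DataFrame],
    markers: list[str],
    fdr_cut: float = 0.05,
) -> MarkerOverlap:
    """Cross-cohort concordant surface markers per comparison, and their
    direction-consistent intersection across the two comparisons.

    Each ``de_*`` argument is a (cohort A, cohort B) pair of per-gene
    DE tables (columns ``t``, ``fdr``).
    """
    per = {
        "MUT_vs_WT": _concordant_markers(*de_mut, markers, fdr_cut),
        "MUTLIKE_vs_WT": _concordant_markers(*de_mutlike, markers, fdr_cut),
    }
    a, b = per["MUT_vs_WT"], per["MUTLIKE_vs_WT"]
    shared = [
        g for g in a.index
        if g in b.index and a.loc[g, "direction"] == b.loc[g, "direction"]
    ]
    inter = a.loc[shared].copy() if shared else pd.DataFrame(columns=["direction"])
    return MarkerOverlap(per_comparison=per, intersection=inter)
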