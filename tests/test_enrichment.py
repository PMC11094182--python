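import numpy as np
import pandas as pd
import pytest

from mutlike.enrichment import (
    RankedList,
    _running_es,
    concordance_filter,
    gsea_preranked,
    rank_genes,
    surface_marker_overlap,
)
from mutlike.io import ExpressionMatrix, log2cpm, cpm


def brute_force_es(statistic, hit_mask, weight):
    """Position-by-position running sum, straight from the definition."""
    r = np.abs(np.asarray(statistic, float)) ** weight
    m = hit_mask.sum()
    n = len(r)
    total = r[hit_mask].sum()
    p_hit, p_miss, best = 0.0, 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            p_hit += r[i] / total
        else:
            p_miss += 1.0 / (n - m)
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


def ranked(n=5, stats=None):
    s = np.array(stats if stats is not None else np.arange(n, 0, -1), float)
    return RankedList([f"g{i}" for i in range(len(s))], s)


class TestRunningSum:
    def test_printed_five_gene_example(self):
        # |r| = (5,4,3,2,1), set at ranks {1,4}: ES = 5/7
        rl = ranked(stats=[5, 4, 3, 2, 1])
        res = gsea_preranked(rl, {"S": ["g0", "g3"]}, n_perm=50, min_size=1)
        assert res.loc["S", "es"] == pytest.approx(5 / 7, abs=1e-12)

    def test_top_set_scores_plus_one(self):
        rl = ranked(n=10)
        res = gsea_preranked(rl, {"TOP": ["g0", "g1", "g2"]}, n_perm=50, min_size=1)
        assert res.loc["TOP", "es"] == pytest.approx(1.0)

    def test_bottom_set_scores_minus_one(self):
        rl = ranked(n=10)
        res = gsea_preranked(rl, {"BOT": ["g7", "g8", "g9"]}, n_perm=50, min_size=1)
        assert res.loc["BOT", "es"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_brute_force_on_random_instances(self, weight):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(6, 21)
            stats = np.sort(rng.normal(size=n))[::-1]
            m = rng.integers(1, n - 1)
            hit_pos = np.sort(rng.choice(n, size=m, replace=False))
            mask = np.zeros(n, bool)
            mask[hit_pos] = True
            weights = np.abs(stats) ** weight
            es, _ = _running_es(hit_pos, weights, n)
            assert es == pytest.approx(
                brute_force_es(stats, mask, weight), abs=1e-12
            )

    def test_es_bounds(self):
        rng = np.random.default_rng(1)
        rl = ranked(stats=np.sort(rng.normal(size=50))[::-1])
        sets = {f"S{i}": [f"g{j}" for j in rng.choice(50, 8, replace=False)]
                for i in range(10)}
        res = gsea_preranked(rl, sets, n_perm=50)
        assert ((res["es"] >= -1) & (res["es"] <= 1)).all()
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()

    def test_whole_list_set_rejected(self):
        rl = ranked(n=5)
        with pytest.raises(ValueError):
            gsea_preranked(rl, {"ALL": [f"g{i}" for i in range(5)]},
                           n_perm=10, min_size=1)

    def test_agrees_with_gseapy_es(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(2)
        stats = np.sort(rng.normal(size=60))[::-1]
        rl = ranked(stats=stats)
        sets = {f"S{i}": [f"g{j}" for j in rng.choice(60, 10, replace=False)]
                for i in range(5)}
        ours = gsea_preranked(rl, sets, n_perm=20)
        rnk = pd.DataFrame({"gene": rl.gene_ids, "score": rl.statistic})
        ref = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=20, min_size=2,
            max_size=500, seed=0, outdir=None, no_plot=True,
        ).res2d.set_index("Term")
        for s in sets:
            assert ours.loc[s, "es"] == pytest.approx(float(ref.loc[s, "ES"]), abs=1e-6)


class TestRankGenes:
    def wrap(self, A, samples):
        return ExpressionMatrix(
            pd.DataFrame(A, index=[f"g{i}" for i in range(A.shape[0])],
                         columns=samples),
            stage="log2cpm",
        )

    def groups(self, samples, k):
        return pd.Series(["A"] * k + ["B"] * (len(samples) - k), index=samples)

    def test_equal_means_rank_zero(self):
        samples = [f"s{i}" for i in range(8)]
        A = np.tile(np.arange(8, dtype=float), (3, 1))
        A[:, 4:] = A[:, :4]  # group B mirrors group A
        rl = rank_genes(self.wrap(A, samples), self.groups(samples, 4), ("A", "B"))
        assert np.allclose(rl.statistic, 0.0)

    def test_group_swap_negates_statistics(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(10)]
        A = rng.normal(size=(6, 10))
        g = self.groups(samples, 5)
        r1 = rank_genes(self.wrap(A, samples), g, ("A", "B"))
        r2 = rank_genes(self.wrap(A, samples), g, ("B", "A"))
        s1 = pd.Series(r1.statistic, index=r1.gene_ids)
        s2 = pd.Series(r2.statistic, index=r2.gene_ids)
        np.testing.assert_allclose(s1, -s2[s1.index], atol=1e-10)
        assert r1.gene_ids == r2.gene_ids[::-1] or np.allclose(s1, 0)

    def test_planted_program_gene_ranks_high(self, small_cohort):
        expr, ann, _, truth = small_cohort
        lc = log2cpm(cpm(expr))
        groups = pd.Series(
            np.where(ann["tp53_status"] == "MUT", "MUT", "WT"), index=ann.index
        )
        rl = rank_genes(lc, groups, ("MUT", "WT"))
        top_decile = set(rl.gene_ids[: len(rl.gene_ids) // 10])
        hits = sum(g in top_decile for g in truth.program_gene_ids)
        assert hits >= len(truth.program_gene_ids) * 0.5


class TestCalibration:
    def test_nominal_p_uniform_under_null(self):
        rng = np.random.default_rng(4)
        stats = np.sort(rng.normal(size=600))[::-1]
        rl = RankedList([f"g{i}" for i in range(600)], stats)
        sets = {
            f"S{i}": [f"g{j}" for j in rng.choice(600, 15, replace=False)]
            for i in range(200)
        }
        res = gsea_preranked(rl, sets, n_perm=200, seed=0)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestConcordance:
    def res(self, rows):
        return pd.DataFrame(rows, columns=["set", "nes", "fdr"]).set_index("set")

    def test_kept_dropped_rules(self):
        a = self.res([["s1", 2.1, 0.01], ["s2", 2.1, 0.01], ["s3", 2.1, 0.01]])
        b = self.res([["s1", 1.8, 0.04], ["s2", -1.8, 0.01], ["s3", 1.8, 0.06]])
        assert concordance_filter(a, b) == ["s1"]

    def test_self_concordance_returns_significant_sets(self):
        rng = np.random.default_rng(5)
        a = self.res([[f"s{i}", rng.normal(), rng.uniform()] for i in range(20)])
        expect = sorted(a.index[a["fdr"] < 0.05])
        assert sorted(concordance_filter(a, a)) == expect


class TestMarkerOverlap:
    def de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "t", "fdr"]).set_index("gene")

    def test_shared_concordant_markers_intersect(self):
        markers = [f"m{i}" for i in range(5)] + ["other"]
        sig = self.de([[f"m{i}", 2.0, 0.01] for i in range(5)] + [["other", 2.0, 0.5]])
        ov = surface_marker_overlap((sig, sig), (sig, sig), markers)
        assert len(ov.intersection) == 5
        assert "other" not in ov.intersection.index

    def test_opposite_direction_excluded(self):
        markers = ["m1"]
        up = self.de([["m1", 2.0, 0.01]])
        down = self.de([["m1", -2.0, 0.01]])
        ov = surface_marker_overlap((up, up), (down, down), markers)
        assert len(ov.intersection) == 0
        assert len(ov.per_comparison["MUT_vs_WT"]) == 1

    def test_empty_marker_list(self):
        sig = self.de([["m1", 2.0, 0.01]])
        ov = surface_marker_overlap((sig, sig), (sig, sig), [])
        assert len(ov.intersection) == 0
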