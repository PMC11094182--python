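"""Gene-set enrichment and surface-marker concordance across cohorts.

Ranks genes (Welch t on log2-CPM) for MUT-vs-WT and MUTLIKE-vs-WT in
each cohort, runs preranked GSEA against the planted program plus
random decoy sets, keeps sets significant with concordant sign in both
cohorts, and intersects concordantly differentially expressed
surface-marker genes between the two comparisons.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mutlike.enrichment import (
    concordance_filter,
    gsea_preranked,
    rank_genes,
    surface_marker_overlap,
)
from mutlike.io import cpm, log2cpm, read_gene_list, write_gmt
from mutlike.pipeline import load_cohort
from mutlike.stats import bh_adjust

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def de_table(rl):
    """Per-gene signed statistic + BH FDR from a ranked list."""
    from scipy import stats as sps

    t = pd.Series(rl.statistic, index=rl.gene_ids, name="t")
    # two-sided normal-approximation p for the Welch statistic
    p = 2 * sps.norm.sf(np.abs(t))
    return pd.DataFrame({"t": t, "fdr": bh_adjust(p)})


def main() -> None:
    cohorts = {}
    for name in ("A", "B"):
        expr, ann, _ = load_cohort(SCRATCH / name)
        groups = pd.read_csv(
            RESULTS / "pipeline" / f"groups_{name}.tsv", sep="\t",
            index_col="sample_id",
        )["group"]
        program = read_gene_list(SCRATCH / name / "program_genes.txt")
        cohorts[name] = (log2cpm(cpm(expr)), groups, program)

    rng = np.random.default_rng(0)
    gene_ids = cohorts["A"][0].gene_ids
    sets = {"PLANTED_PROGRAM": cohorts["A"][2]}
    for i in range(20):
        sets[f"RANDOM_{i}"] = list(rng.choice(gene_ids, 50, replace=False))
    write_gmt(sets, RESULTS / "gene_sets.gmt")

    enr, rls = {}, {}
    for name, (lc, groups, _) in cohorts.items():
        for pair in (("MUT", "WT"), ("MUTLIKE", "WT")):
            rl = rank_genes(lc, groups, pair)
            rls[name, pair[0]] = rl
            res = gsea_preranked(rl, sets, n_perm=500, seed=1)
            enr[name, pair[0]] = res
            res.to_csv(RESULTS / f"gsea_{name}_{pair[0]}_vs_WT.tsv", sep="\t",
                       lineterminator="\n")
            print(f"cohort {name} {pair[0]} vs WT: program NES "
                  f"{res.loc['PLANTED_PROGRAM', 'nes']:.2f}, "
                  f"FDR {res.loc['PLANTED_PROGRAM', 'fdr']:.3f}")

    for grp in ("MUT", "MUTLIKE"):
        conc = concordance_filter(enr["A", grp], enr["B", grp])
        print(f"{grp} vs WT concordant across cohorts (FDR<0.05 both): {conc}")

    # surface markers: the first 25 program genes plus 25 decoys
    markers = cohorts["A"][2][:25] + [g for g in gene_ids if g not in cohorts["A"][2]][:25]
    ov = surface_marker_overlap(
        (de_table(rls["A", "MUT"]), de_table(rls["B", "MUT"])),
        (de_table(rls["A", "MUTLIKE"]), de_table(rls["B", "MUTLIKE"])),
        markers,
    )
    nm = len(ov.per_comparison["MUT_vs_WT"])
    nl = len(ov.per_comparison["MUTLIKE_vs_WT"])
    print(f"surface markers concordant in both cohorts: {nm} (MUT), {nl} (MUTLIKE), "
          f"{len(ov.intersection)} shared with agreeing direction")
    ov.intersection.reset_index().to_csv(
        RESULTS / "marker_intersection.tsv", sep="\t", index=False, lineterminator="\n"
    )


if __name__ == "__main__":
    main()
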