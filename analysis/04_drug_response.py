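"""Ex-vivo drug-response comparison across subtypes.

AUC values are z-scored per drug and sign-flipped (high z = sensitive),
then each drug is compared MUT-vs-WT and MUTLIKE-vs-WT with pooled
t-tests and BH adjustment across the panel. The generator plants a
resistance shift that rises with program activation, so both activated
classes should show depressed sensitivity z-scores panel-wide.
"""

from pathlib import Path

import pandas as pd

from mutlike.pipeline import load_cohort
from mutlike.stats import compare_table, drug_auc_zscores

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    _, ann, drugs = load_cohort(SCRATCH / "A")
    groups = pd.read_csv(
        RESULTS / "pipeline" / "groups_A.tsv", sep="\t", index_col="sample_id"
    )["group"]
    aucz = drug_auc_zscores(drugs)

    out = []
    for pair in (("MUT", "WT"), ("MUTLIKE", "WT")):
        t = compare_table(aucz, groups, pair)
        t["comparison"] = "{}_vs_{}".format(*pair)
        resistant = (t["group1_mean"] < t["group2_mean"]) & (t["fdr"] < 0.05)
        print(f"{pair[0]} vs WT: {resistant.sum()}/{len(t)} drugs significantly "
              f"more resistant (lower sensitivity z, FDR<0.05)")
        out.append(t.reset_index())
    pd.concat(out, ignore_index=True).to_csv(
        RESULTS / "drug_comparisons_A.tsv", sep="\t", index=False, lineterminator="\n"
    )


if __name__ == "__main__":
    main()
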