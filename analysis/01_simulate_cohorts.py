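"""Simulate the two study cohorts.

Generates a discovery cohort (A) and an independent validation cohort
(B) from the same generative law — shared planted program and gene
baselines, different patients — and writes them as TSV bundles under
scratch/cohorts/. Cohort A stands in for a large mixed-stage cohort,
cohort B for an external diagnostic cohort.
"""

import dataclasses
from pathlib import Path

from mutlike import SimulationConfig, generate_cohort, write_cohort

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"
SEED_A, SEED_B = 11, 1011


def main() -> None:
    cfgA = SimulationConfig(seed=SEED_A)
    cfgB = dataclasses.replace(cfgA, seed=SEED_B)
    for name, cfg in [("A", cfgA), ("B", cfgB)]:
        expr, ann, drugs, truth = generate_cohort(cfg)
        out = SCRATCH / name
        write_cohort(out, expr, ann, drugs, truth)
        cfg.to_json(out / "config.json")
        n_mut = (ann["tp53_status"] == "MUT").sum()
        n_ml = truth.table["true_mutlike"].sum()
        print(
            f"cohort {name}: {expr.shape[0]} genes x {expr.shape[1]} samples | "
            f"{n_mut} mutant, {n_ml} hidden mutant-like wild-type, "
            f"{expr.shape[1] - n_mut - n_ml} other wild-type -> {out}"
        )


if __name__ == "__main__":
    main()
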